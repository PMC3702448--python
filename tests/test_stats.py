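"""Mixed-model reference statistics against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiorelax.config import load_reference_config
from cardiorelax.phantom import build_cohort
from cardiorelax.stats import (
    ModelError,
    bland_altman,
    cofactor_correlations,
    cofactor_split_means,
    fit_reference_model,
    howe_k_factor,
    ls_means,
    scatter_factor,
    tolerance_interval,
)
from conftest import synthetic_segment_table


def balanced_table(mus, sigma_s, sigma_e, n_subjects, seed=0, map_kind="t2"):
    """Balanced slice-level table with known variance components."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, sigma_s)
        hr = rng.normal(70, 6)
        for sl, mu in mus.items():
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "map_kind": map_kind,
                    "slice": sl,
                    "segment": 1,
                    "value": np.exp(np.log(mu) + u + rng.normal(0, sigma_e)),
                    "eligible": True,
                    "n_pixels": 100,
                    "age_band": ["20-39", "40-59", "60-80"][i % 3],
                    "sex": "MF"[i % 2],
                    "heart_rate": hr,
                    "systolic_bp": rng.normal(132, 12),
                    "diastolic_bp": rng.normal(72, 11),
                }
            )
    return pd.DataFrame(rows)


MUS = {"base": 44.1, "middle": 45.1, "apex": 46.9}


class TestReferenceModel:
    def test_no_subject_variance_collapses_to_geometric_means(self):
        t = balanced_table(MUS, sigma_s=0.0, sigma_e=1e-6, n_subjects=12, seed=1)
        m = fit_reference_model(t, "t2", unit="slice", cofactors=())
        for sl, mu in MUS.items():
            df = t[t["slice"] == sl]
            direct = np.exp(np.mean(np.log(df["value"])))
            assert ls_means(m, sl)["mean"] == pytest.approx(direct, rel=1e-6)
            assert ls_means(m, sl)["mean"] == pytest.approx(mu, rel=1e-3)

    def test_variance_component_recovery(self):
        # the REML estimate must track each draw's empirical subject SD, and
        # across seeds average to the generating scatter 1.08 within 0.02
        recovered = []
        for seed in range(8):
            t = balanced_table(
                MUS, sigma_s=np.log(1.08), sigma_e=0.005, n_subjects=40, seed=seed
            )
            m = fit_reference_model(t, "t2", unit="slice", cofactors=())
            logv = np.log(t["value"].to_numpy())
            resid = logv - t.groupby("slice")["value"].transform(
                lambda v: np.log(v).mean()
            )
            empirical = resid.groupby(t["subject_id"]).mean().std(ddof=1)
            total_emp = float(np.sqrt(empirical**2 + 0.005**2))
            assert m.sigma_total == pytest.approx(total_emp, abs=0.01)
            recovered.append(m.scatter_total)
        assert np.mean(recovered) == pytest.approx(1.08, abs=0.02)

    def test_reml_matches_anova_moments_on_balanced_table(self):
        # balanced one-way layout: method-of-moments oracle
        t = balanced_table(MUS, sigma_s=0.08, sigma_e=0.03, n_subjects=30, seed=3)
        m = fit_reference_model(t, "t2", unit="slice", cofactors=())
        logv = np.log(t["value"].to_numpy())
        df = t.assign(logv=logv)
        # remove slice effects, then one-way ANOVA on subjects
        df["resid"] = df["logv"] - df.groupby("slice")["logv"].transform("mean")
        k = 3
        n = df["subject_id"].nunique()
        subj_means = df.groupby("subject_id")["resid"].mean()
        msb = k * subj_means.var(ddof=1)
        msw = (
            df.groupby("subject_id")["resid"]
            .apply(lambda x: ((x - x.mean()) ** 2).sum())
            .sum()
            / (n * (k - 1))
        )
        s2e_mom = msw * (n * (k - 1)) / (n * (k - 1) - (k - 1))  # slice df correction
        s2s_mom = (msb - msw) / 1.0 / k * k / k
        # compare at loose analytic tolerance; both estimate the same target
        assert m.sigma2_resid == pytest.approx(msw, rel=0.15)
        assert m.sigma2_subject == pytest.approx(max((msb - msw) / k, 0), rel=0.15)
        _ = s2e_mom, s2s_mom

    def test_backtransform_preserves_level_ordering(self):
        t = balanced_table(MUS, sigma_s=0.05, sigma_e=0.01, n_subjects=25, seed=4)
        m = fit_reference_model(t, "t2", unit="slice", cofactors=())
        tab = m.ls_means.set_index("slice")
        assert tab.loc["base", "mean"] < tab.loc["middle", "mean"] < tab.loc["apex", "mean"]
        assert (tab["log_mean"].rank() == tab["mean"].rank()).all()

    def test_multiplicative_rescaling_invariance(self):
        t = balanced_table(MUS, sigma_s=0.06, sigma_e=0.02, n_subjects=20, seed=5)
        m1 = fit_reference_model(t, "t2", unit="slice", cofactors=())
        t2 = t.assign(value=t["value"] * 3.0)
        m2 = fit_reference_model(t2, "t2", unit="slice", cofactors=())
        assert m2.scatter_total == pytest.approx(m1.scatter_total, rel=1e-5)
        for sl in MUS:
            assert ls_means(m2, sl)["mean"] == pytest.approx(
                3.0 * ls_means(m1, sl)["mean"], rel=1e-5
            )

    def test_strong_hr_effect_retained(self):
        # detection machinery check with an unambiguous effect size
        from dataclasses import replace

        cfg = load_reference_config(n_total=40, hr_effect=True)
        strong = {k: {sl: 0.85 for sl in v} for k, v in cfg.hr_effect.items()}
        cfg = replace(cfg, hr_effect=strong)
        subjects = build_cohort(cfg, seed=8)
        t = synthetic_segment_table(subjects, "t2", noise_sd=0.3, seed=8)
        m = fit_reference_model(t, "t2", unit="slice")
        assert "hr_high" in m.retained_cofactors
        assert m.cofactor_pvalues["hr_high"] < 0.05

    def test_hr_split_means_recover_group_values(self):
        cfg = load_reference_config(n_total=40, hr_effect=True)
        subjects = build_cohort(cfg, seed=8)
        t = synthetic_segment_table(subjects, "t2", noise_sd=0.3, seed=8)
        split = cofactor_split_means(t, "t2", "heart_rate")
        above = split["above"].set_index("slice")["mean"]
        below = split["below"].set_index("slice")["mean"]
        assert (above < below).all()
        # the estimator must match each group's empirical geometric mean ...
        med = split["split"]
        for name, grp in (("below", below), ("above", above)):
            sel = [
                s for s in subjects
                if (s.heart_rate <= med) == (name == "below")
            ]
            emp = np.exp(np.mean([np.log(s.segment_truth("t2", 1)) for s in sel]))
            assert grp["base"] == pytest.approx(emp, rel=0.01)
        # ... and the group ratio recovers the configured effect size
        assert above["base"] / below["base"] == pytest.approx(42.8 / 45.8, rel=0.08)

    def test_null_split_leaves_pooled_mean(self):
        # splitting on a covariate independent of value barely moves means
        cfg = load_reference_config(n_total=40)
        subjects = build_cohort(cfg, seed=13)
        t = synthetic_segment_table(subjects, "t2", noise_sd=0.3, seed=13)
        m = fit_reference_model(t, "t2", unit="slice", cofactors=())
        split = cofactor_split_means(t, "t2", "systolic_bp")
        pooled = ls_means(m, "base")["mean"]
        for grp in ("above", "below"):
            grp_mean = split[grp].set_index("slice").loc["base", "mean"]
            assert grp_mean == pytest.approx(pooled, rel=0.05)

    def test_unknown_level_and_tiny_cohort_errors(self):
        t = balanced_table(MUS, 0.05, 0.01, 10, seed=6)
        m = fit_reference_model(t, "t2", unit="slice", cofactors=())
        with pytest.raises(KeyError):
            ls_means(m, "ventricle")
        single = t[t["subject_id"] == "S000"]
        with pytest.raises(ModelError):
            fit_reference_model(single, "t2", unit="slice", cofactors=())

    def test_segment_unit_model(self):
        cfg = load_reference_config(n_total=20)
        subjects = build_cohort(cfg, seed=9)
        t = synthetic_segment_table(subjects, "t1_pre", noise_sd=2.0, seed=9)
        m = fit_reference_model(t, "t1_pre", unit="segment", cofactors=())
        assert len(m.ls_means) == 16
        base_val = cfg.reference_values["t1_pre"]["base"]
        for seg in range(1, 7):
            assert ls_means(m, seg)["mean"] == pytest.approx(base_val, rel=0.03)


class TestToleranceInterval:
    def test_zero_sigma_collapses_to_mean(self):
        lo, hi = tolerance_interval(np.log(44.1), 0.0, 60)
        assert lo == hi == pytest.approx(44.1)

    def test_multiplicative_symmetry(self):
        mean = 44.1
        lo, hi = tolerance_interval(np.log(mean), 0.08, 60)
        assert hi / mean == pytest.approx(mean / lo, rel=1e-9)

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            tolerance_interval(3.0, 0.1, 1)

    def test_howe_factor_reasonable(self):
        # at n = 60, 90% coverage / 95% confidence, k is slightly above z_0.95
        k = howe_k_factor(60)
        assert 1.645 < k < 2.1

    def test_monte_carlo_coverage(self):
        # content >= 90% in >= ~95% of replicates for log-normal populations
        rng = np.random.default_rng(10)
        n, reps = 60, 10_000
        sigma, mu = 0.08, np.log(44.1)
        x = rng.normal(mu, sigma, size=(reps, n))
        m = x.mean(axis=1)
        s = x.std(axis=1, ddof=1)
        k = howe_k_factor(n)
        from scipy.stats import norm

        content = norm.cdf((m + k * s - mu) / sigma) - norm.cdf((m - k * s - mu) / sigma)
        success = (content >= 0.90).mean()
        # nominal 95% confidence; binomial MC error at 10^4 reps is ~0.2%
        assert success == pytest.approx(0.95, abs=0.005)
        assert success >= 0.945


class TestScatterFactor:
    def test_identical_values_give_one(self):
        t = balanced_table(MUS, 0.0, 1e-9, 10, seed=7)
        m = fit_reference_model(t, "t2", unit="slice", cofactors=())
        assert scatter_factor(m) == pytest.approx(1.0, abs=1e-3)

    def test_matches_hand_computed_sd(self):
        # no grouping: log values 0, 0.1, 0.2 -> exp(sd) oracle
        logs = np.array([0.0, 0.1, 0.2])
        oracle = float(np.exp(logs.std(ddof=1)))
        rows = []
        for i, lv in enumerate(logs):
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "map_kind": "t2",
                    "slice": "base",
                    "segment": 1,
                    "value": float(np.exp(lv)),
                    "eligible": True,
                    "n_pixels": 1,
                    "age_band": "20-39",
                    "sex": "M",
                    "heart_rate": 70.0,
                    "systolic_bp": 130.0,
                    "diastolic_bp": 70.0,
                }
            )
        t = pd.DataFrame(rows)
        m = fit_reference_model(t, "t2", unit="slice", cofactors=())
        assert m.sigma_total == pytest.approx(logs.std(ddof=1), rel=0.2)
        assert scatter_factor(m) == pytest.approx(oracle, abs=0.02)

    def test_generator_recovery_at_n40(self):
        cfg = load_reference_config(n_total=40)
        subjects = build_cohort(cfg, seed=12)
        t = synthetic_segment_table(subjects, "t2", noise_sd=0.3, seed=12)
        m = fit_reference_model(t, "t2", unit="slice")
        assert scatter_factor(m) == pytest.approx(1.08, abs=0.02)
        assert scatter_factor(m, "subject") <= scatter_factor(m, "total")


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.sd == 0.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_zero_variance_r_undefined(self):
        res = bland_altman([5.0, 5.0, 5.0], [5.1, 4.9, 5.0])
        assert np.isnan(res.pearson_r)

    def test_hand_computed_pairs(self):
        x, y = np.array([10.0, 20.0, 30.0]), np.array([12.0, 19.0, 33.0])
        d = y - x
        res = bland_altman(x, y)
        assert res.bias == pytest.approx(d.mean())
        assert res.sd == pytest.approx(d.std(ddof=1))
        assert res.loa_upper == pytest.approx(res.bias + 1.96 * res.sd)

    @given(st.lists(st.floats(1.0, 100.0), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_limits_symmetric_about_bias(self, values):
        x = np.asarray(values)
        res = bland_altman(x, x + 1.5)
        assert res.loa_upper - res.bias == pytest.approx(res.bias - res.loa_lower)


class TestCofactorCorrelations:
    def test_self_and_monotone_pairs(self, cohort):
        from cardiorelax.phantom import cohort_table

        tbl = cohort_table(cohort).rename(columns={})
        corr = cofactor_correlations(tbl)
        assert corr.loc["age", "age"] == 1.0
        tbl2 = tbl.assign(systolic_bp=np.exp(tbl["age"] / 10.0))  # monotone in age
        corr2 = cofactor_correlations(tbl2)
        assert corr2.loc["age", "systolic_bp"] == pytest.approx(1.0)

    def test_matches_exhaustive_rank_oracle(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(8)],
                "age": rng.uniform(20, 80, 8),
                "heart_rate": rng.uniform(50, 100, 8),
                "systolic_bp": rng.uniform(100, 160, 8),
                "diastolic_bp": rng.uniform(60, 90, 8),
            }
        )
        corr = cofactor_correlations(df)

        def spearman_oracle(a, b):
            ra = np.argsort(np.argsort(a)).astype(float)
            rb = np.argsort(np.argsort(b)).astype(float)
            return np.corrcoef(ra, rb)[0, 1]

        assert corr.loc["age", "heart_rate"] == pytest.approx(
            spearman_oracle(df["age"].to_numpy(), df["heart_rate"].to_numpy())
        )

    def test_constant_cofactor_flagged_nan(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(5)],
                "age": [30.0, 40, 50, 60, 70],
                "heart_rate": [70.0] * 5,
                "systolic_bp": [120.0, 125, 130, 135, 140],
                "diastolic_bp": [70.0, 71, 72, 73, 74],
            }
        )
        corr = cofactor_correlations(df)
        assert np.isnan(corr.loc["age", "heart_rate"])
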