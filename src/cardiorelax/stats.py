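"""Reference-value statistics on log-transformed relaxation times.

The analysis model is a linear mixed model on log values::

    log(value) = unit fixed effects (slice or segment)
               + retained cofactors + subject random intercept + error

fitted by REML.  Candidate cofactors are age band, sex, heart rate
(dichotomised at the cohort median) and systolic/diastolic blood pressure;
they are eliminated backwards while the least significant Wald p-value is
>= 0.05 (unit effects are never eliminated).  All reported quantities are
back-transformed with the exponential:

* least-square means with 95% confidence intervals,
* 95%-confidence / 90%-coverage normal tolerance intervals (Howe's
  approximation for the k factor),
* the scatter factor exp(sqrt(sigma_s^2 + sigma_e^2)) — the back-transformed
  total SD, a multiplicative analogue of the coefficient of variation.

Observer agreement is assessed by Bland-Altman statistics and Pearson
correlation; cofactor inter-correlation by Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelResult",
    "AgreementResult",
    "prepare_model_frame",
    "fit_reference_model",
    "ls_means",
    "tolerance_interval",
    "howe_k_factor",
    "scatter_factor",
    "bland_altman",
    "cofactor_split_means",
    "cofactor_correlations",
    "COFACTORS",
]

#: candidate cofactors and their formula terms
COFACTORS = {
    "age_band": "C(age_band)",
    "sex": "C(sex)",
    "hr_high": "hr_high",
    "systolic_bp": "systolic_bp",
    "diastolic_bp": "diastolic_bp",
}

ALPHA = 0.05


class ModelError(RuntimeError):
    """Singular or otherwise unusable model."""


@dataclass
class ModelResult:
    """Fitted log-scale mixed model and its back-transformed summaries."""

    map_kind: str
    unit: str                         # "slice" | "segment"
    n_subjects: int
    n_obs: int
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    sigma2_subject: float
    sigma2_resid: float
    ls_means: pd.DataFrame            # level, log_mean, mean, ci/tolerance bounds
    scatter_total: float
    scatter_subject: float
    retained_cofactors: list = field(default_factory=list)
    cofactor_pvalues: dict = field(default_factory=dict)
    elimination_trace: list = field(default_factory=list)
    hr_split: float = float("nan")

    @property
    def sigma_total(self) -> float:
        return float(np.sqrt(self.sigma2_subject + self.sigma2_resid))


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement of paired measurements."""

    bias: float                       # mean difference, ms
    sd: float                         # SD of differences, ms
    loa_lower: float                  # bias - 1.96 SD
    loa_upper: float                  # bias + 1.96 SD
    pearson_r: float                  # NaN when undefined (zero variance)
    n: int


# ---------------------------------------------------------------------------
# data preparation


def prepare_model_frame(
    table: pd.DataFrame,
    map_kind: str,
    unit: str = "slice",
    hr_split: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Eligible-rows analysis frame for one map type.

    For ``unit='slice'`` segment values are pooled into pixel-count-weighted
    per-slice means.  Returns the frame (with ``log_value`` and the binary
    ``hr_high``) and the heart-rate split used (cohort median of
    subject-level heart rates unless given).
    """
    if unit not in ("slice", "segment"):
        raise ValueError("unit must be 'slice' or 'segment'")
    df = table[(table["map_kind"] == map_kind) & table["eligible"]].copy()
    df = df[np.isfinite(df["value"]) & (df["value"] > 0)]
    if df.empty:
        raise ModelError(f"no eligible rows for map kind {map_kind!r}")
    covars = ["age_band", "sex", "heart_rate", "systolic_bp", "diastolic_bp"]
    if unit == "slice":
        weights = df["n_pixels"] if "n_pixels" in df else pd.Series(1.0, index=df.index)
        df = df.assign(_w=weights)
        grouped = df.groupby(["subject_id", "slice"], sort=False)
        agg = grouped.apply(
            lambda g: pd.Series(
                {"value": np.average(g["value"], weights=g["_w"]),
                 **{c: g[c].iloc[0] for c in covars}}
            ),
            include_groups=False,
        ).reset_index()
        df = agg
    df["log_value"] = np.log(df["value"].astype(float))
    subj_hr = df.groupby("subject_id")["heart_rate"].first()
    if hr_split is None:
        hr_split = float(subj_hr.median())
    df["hr_high"] = (df["heart_rate"] > hr_split).astype(int)
    return df, hr_split


# ---------------------------------------------------------------------------
# mixed model


def _unit_term(unit: str) -> str:
    return "C(slice)" if unit == "slice" else "C(segment)"


def _fit_mixedlm(df: pd.DataFrame, unit: str, cofactor_terms: list[str]):
    rhs = " + ".join([f"0 + {_unit_term(unit)}"] + cofactor_terms)
    formula = f"log_value ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["subject_id"])
        try:
            res = model.fit(reml=True, method="lbfgs")
            if not _fe_solution_sane(res):
                res = model.fit(reml=True, method="powell")
        except np.linalg.LinAlgError:
            try:  # gradient-free fallback for ill-conditioned designs
                res = model.fit(reml=True, method="powell")
            except np.linalg.LinAlgError as exc:
                raise ModelError(f"singular design: {exc}") from exc
    return res


def _fe_solution_sane(res) -> bool:
    """Guard against optimizer pathologies in near-degenerate fits.

    The fixed-effect residual sum of squares can never be dramatically
    worse than the plain OLS solution; if it is, the optimizer silently
    diverged (seen with lbfgs when variance components are ~0).
    """
    X = res.model.exog
    y = res.model.endog
    fe = np.asarray(res.fe_params)
    rss_fe = float(((y - X @ fe) ** 2).sum())
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(((y - X @ beta_ols) ** 2).sum())
    return rss_fe <= 2.0 * rss_ols + 1e-8 * float((y**2).sum() + 1.0)


def _term_slices(res) -> dict:
    di = res.model.data.design_info
    return dict(zip(di.term_names, (di.term_name_slices[t] for t in di.term_names)))


def _wald_p(res, term: str, df_denom: int) -> float:
    """Joint Wald F test of all columns of a formula term."""
    slices = _term_slices(res)
    if term not in slices:
        raise ModelError(f"term {term!r} not in model")
    sl = slices[term]
    b = np.asarray(res.fe_params)[sl]
    V = np.asarray(res.cov_params())[: len(res.fe_params), : len(res.fe_params)][
        sl, sl
    ]
    q = b.size
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"singular covariance for term {term!r}") from exc
    return float(sps.f.sf(stat / q, q, max(df_denom, 3)))


def fit_reference_model(
    table: pd.DataFrame,
    map_kind: str,
    unit: str = "slice",
    cofactors: tuple[str, ...] = tuple(COFACTORS),
    hr_split: float | None = None,
    coverage: float = 0.90,
    confidence: float = 0.95,
) -> ModelResult:
    """Fit the log-scale reference mixed model with backward elimination.

    The cofactor with the largest Wald p >= 0.05 is removed iteratively;
    unit (slice/segment) effects always stay.  Wald tests use conservative
    between-subject denominator degrees of freedom.
    """
    df, split = prepare_model_frame(table, map_kind, unit, hr_split)
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 2:
        raise ModelError("at least two subjects required")
    for cof in cofactors:
        if cof not in COFACTORS:
            raise ValueError(f"unknown cofactor {cof!r}")
    retained = [c for c in cofactors if df[_cof_column(c)].nunique() > 1]
    trace: list[tuple[str, float]] = []
    while True:
        terms = [COFACTORS[c] for c in retained]
        res = _fit_mixedlm(df, unit, terms)
        if not retained:
            pvals = {}
            break
        n_cof_cols = sum(
            sl.stop - sl.start
            for t, sl in _term_slices(res).items()
            if t in terms
        )
        df_denom = n_subjects - 1 - n_cof_cols
        pvals = {c: _wald_p(res, COFACTORS[c], df_denom) for c in retained}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] >= ALPHA:
            trace.append((worst, pvals[worst]))
            retained.remove(worst)
        else:
            break

    sigma2_subject = float(np.asarray(res.cov_re)[0, 0])
    sigma2_resid = float(res.scale)
    lsm = _ls_means_table(
        res, df, unit, n_subjects, sigma2_subject, sigma2_resid,
        coverage, confidence,
    )
    return ModelResult(
        map_kind=map_kind,
        unit=unit,
        n_subjects=n_subjects,
        n_obs=len(df),
        fe_params=res.fe_params,
        cov_fe=pd.DataFrame(
            np.asarray(res.cov_params())[: len(res.fe_params), : len(res.fe_params)],
            index=res.fe_params.index,
            columns=res.fe_params.index,
        ),
        sigma2_subject=sigma2_subject,
        sigma2_resid=sigma2_resid,
        ls_means=lsm,
        scatter_total=float(np.exp(np.sqrt(sigma2_subject + sigma2_resid))),
        scatter_subject=float(np.exp(np.sqrt(sigma2_subject))),
        retained_cofactors=retained,
        cofactor_pvalues=pvals,
        elimination_trace=trace,
        hr_split=split,
    )


def _cof_column(cofactor: str) -> str:
    return cofactor


def _ls_means_table(
    res, df, unit, n_subjects, s2_subj, s2_resid, coverage, confidence
) -> pd.DataFrame:
    """Marginal (least-square) means per unit level.

    The log-scale marginal mean averages the design row over the observed
    levels of retained categorical cofactors (equal weights) with
    continuous cofactors at their subject-level mean, then exponentiates.
    """
    di = res.model.data.design_info
    level_col = "slice" if unit == "slice" else "segment"
    levels = list(dict.fromkeys(df[level_col]))
    sigma_total = float(np.sqrt(s2_subj + s2_resid))
    k = howe_k_factor(n_subjects, coverage, confidence)
    fe = np.asarray(res.fe_params)
    V = np.asarray(res.cov_params())[: fe.size, : fe.size]
    rows = []
    for level in levels:
        grid = _reference_grid(df, level_col, level)
        (X,) = build_design_matrices([di], grid)
        L = np.asarray(X).mean(axis=0)
        log_mean = float(L @ fe)
        se = float(np.sqrt(L @ V @ L))
        rows.append(
            {
                level_col: level,
                "log_mean": log_mean,
                "se_log": se,
                "mean": np.exp(log_mean),
                "ci_lower": np.exp(log_mean - 1.96 * se),
                "ci_upper": np.exp(log_mean + 1.96 * se),
                "tol_lower": np.exp(log_mean - k * sigma_total),
                "tol_upper": np.exp(log_mean + k * sigma_total),
            }
        )
    return pd.DataFrame(rows)


def _reference_grid(df: pd.DataFrame, level_col: str, level) -> pd.DataFrame:
    """Cartesian reference grid: the focal level crossed with cofactor levels."""
    frames = {level_col: [level]}
    for cat in ("age_band", "sex"):
        if cat in df:
            frames[cat] = sorted(df[cat].unique())
    if "hr_high" in df:
        frames["hr_high"] = sorted(df["hr_high"].unique())
    grid = None
    for col, vals in frames.items():
        part = pd.DataFrame({col: vals})
        grid = part if grid is None else grid.merge(part, how="cross")
    for cont in ("systolic_bp", "diastolic_bp", "heart_rate"):
        if cont in df:
            grid[cont] = df.groupby("subject_id")[cont].first().mean()
    if level_col == "segment":
        # keep only segments, slice is implied
        grid["slice"] = df.loc[df["segment"] == level, "slice"].iloc[0]
    return grid


def ls_means(model: ModelResult, level=None):
    """Back-transformed least-square mean(s) of a fitted model.

    With ``level`` given returns that row; otherwise the full table.
    Level ordering is preserved and the back-transformation is monotone, so
    ordering of levels on the log scale carries over.
    """
    table = model.ls_means
    if level is None:
        return table
    col = table.columns[0]
    hit = table[table[col] == level]
    if hit.empty:
        raise KeyError(f"unknown level {level!r}")
    return hit.iloc[0]


# ---------------------------------------------------------------------------
# tolerance intervals and scatter


def howe_k_factor(n: int, coverage: float = 0.90, confidence: float = 0.95) -> float:
    """Two-sided normal tolerance factor, Howe's approximation.

    k = z_{(1+P)/2} sqrt(nu (1 + 1/n) / chi2_{1-gamma, nu}), nu = n - 1.
    """
    if n < 2:
        raise ValueError("tolerance interval requires n >= 2")
    nu = n - 1
    z = sps.norm.ppf((1.0 + coverage) / 2.0)
    chi2 = sps.chi2.ppf(1.0 - confidence, nu)
    return float(z * np.sqrt(nu * (1.0 + 1.0 / n) / chi2))


def tolerance_interval(
    log_mean: float,
    sigma_total: float,
    n_subjects: int,
    coverage: float = 0.90,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Back-transformed two-sided normal tolerance interval.

    Computed on the log scale and exponentiated, hence multiplicatively
    symmetric about the geometric mean: upper/mean = mean/lower.
    """
    if sigma_total < 0:
        raise ValueError("sigma_total must be >= 0")
    k = howe_k_factor(n_subjects, coverage, confidence)
    return (
        float(np.exp(log_mean - k * sigma_total)),
        float(np.exp(log_mean + k * sigma_total)),
    )


def scatter_factor(model: ModelResult, mode: str = "total") -> float:
    """Back-transformed SD: exp(sqrt(s2_subj + s2_resid)) or exp(sigma_s)."""
    if mode == "total":
        return model.scatter_total
    if mode == "subject":
        return model.scatter_subject
    raise ValueError("mode must be 'total' or 'subject'")


# ---------------------------------------------------------------------------
# agreement and cofactor structure


def bland_altman(values1, values2) -> AgreementResult:
    """Bland-Altman bias/limits and Pearson r of paired measurements.

    Differences are replicate2 - replicate1.  With zero variance in either
    series the correlation is undefined and reported as NaN.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D series of equal length required")
    if x.size < 2:
        raise ValueError("at least two pairs required")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if x.std() == 0 or y.std() == 0:
        r = float("nan")
    else:
        r = float(sps.pearsonr(x, y)[0])
    return AgreementResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        pearson_r=r,
        n=int(x.size),
    )


def cofactor_split_means(
    table: pd.DataFrame,
    map_kind: str,
    cofactor: str = "heart_rate",
    split: float | None = None,
    unit: str = "slice",
) -> dict:
    """Group-wise back-transformed means via the reference model per group.

    The cohort is split at ``split`` (the subject-level median of the
    cofactor when not given); the reference model — without the split
    cofactor — is fitted separately in each group.  Returns
    ``{"below": ls-mean table, "above": ls-mean table, "split": value}``.
    """
    df = table[(table["map_kind"] == map_kind) & table["eligible"]]
    if df.empty:
        raise ModelError(f"no eligible rows for {map_kind!r}")
    subj_vals = df.groupby("subject_id")[cofactor].first()
    if split is None:
        split = float(subj_vals.median())
    groups = {
        "below": df[df[cofactor] <= split],
        "above": df[df[cofactor] > split],
    }
    out = {"split": split}
    drop = {"heart_rate": "hr_high"}.get(cofactor, cofactor)
    cofs = tuple(c for c in COFACTORS if c != drop)
    for name, sub in groups.items():
        if sub["subject_id"].nunique() < 2:
            raise ModelError(f"{name}-split group is empty or has one subject")
        out[name] = fit_reference_model(sub, map_kind, unit, cofactors=cofs).ls_means
    return out


def cofactor_correlations(
    cohort: pd.DataFrame,
    columns: tuple[str, ...] = ("age", "heart_rate", "systolic_bp", "diastolic_bp"),
) -> pd.DataFrame:
    """Spearman rank correlations among subject-level numeric cofactors.

    Constant cofactors yield NaN entries (undefined ranks).
    """
    subj = cohort.groupby("subject_id")[list(columns)].first()
    if len(subj) < 3:
        raise ValueError("at least three subjects required")
    return subj.corr(method="spearman")

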