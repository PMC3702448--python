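"""End-to-end reference experiment: simulate -> register -> fit -> segment
-> QC -> statistics.

``run_reference_experiment`` drives the full pipeline on a simulated cohort
and returns every table the reference analysis produces: the long-format
segment table, QC reports and summary, per-map mixed models with
back-transformed least-square means and tolerance intervals, the per-slice
reference table, a 16-entry bulls-eye table, observer-agreement results
and, when the heart-rate effect is enabled, the median-split group means.

The run is fully reproducible: every random stage draws from a seed
sequence derived from the single pipeline seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aha import (
    aha_segment_mask,
    contours_from_truth,
    roi_mask_from_contours,
    segment_statistics,
    slice_statistics,
)
from .config import (
    MAP_KINDS,
    SLICES,
    PipelineConfig,
    load_observer_settings,
)
from .phantom import (
    apply_motion,
    build_cohort,
    cohort_table,
    inject_artifact,
    random_shifts,
    render_ground_truth,
    simulate_molli_series,
    simulate_observer_remeasurement,
    simulate_t2prep_series,
)
from .qc import flag_artifact_pixels, segment_eligibility, summarize_qc
from .registration import register_series
from .relaxometry import fit_t1_map, fit_t2_map
from .stats import (
    ModelResult,
    bland_altman,
    cofactor_correlations,
    cofactor_split_means,
    fit_reference_model,
)

__all__ = ["ReportBundle", "run_reference_experiment", "write_report_bundle"]


@dataclass
class ReportBundle:
    """Everything one reference experiment produces."""

    cohort: pd.DataFrame
    segment_table: pd.DataFrame
    qc_reports: pd.DataFrame
    qc_summary: dict
    models: dict                      # map kind -> ModelResult (per-slice unit)
    reference_table: pd.DataFrame     # per map kind x slice: LS mean, TI, min-max
    bullseye: pd.DataFrame            # per-segment LS means
    agreement: dict                   # map kind -> {intra, inter} AgreementResult
    hr_split: dict | None             # map kind -> cofactor_split_means output
    provenance: dict = field(default_factory=dict)
    cofactor_corr: pd.DataFrame | None = None  # Spearman, subject-level


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def run_reference_experiment(
    config: PipelineConfig,
    bullseye_models: bool = True,
    observer_subjects: int = 20,
    cofactors: tuple[str, ...] | None = None,
) -> ReportBundle:
    """Run the full pipeline under ``config`` and collect all reports."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    seed_cohort, seed_subjects, seed_observer = root.spawn(3)
    subjects = build_cohort(config.cohort, seed=seed_cohort)
    geometry = config.geometry
    thresholds = config.qc_thresholds

    # geometry-level masks are shared by all subjects
    rois, segmasks = {}, {}
    for sl in SLICES:
        contours = contours_from_truth(geometry, sl, config.erosion_fraction)
        roi = roi_mask_from_contours(contours, geometry)
        rois[sl] = roi
        segmasks[sl] = aha_segment_mask(
            roi,
            geometry.rv_insertion_angle,
            sl,
            centroid=((geometry.grid_size - 1) / 2.0,) * 2,
            pixel_spacing_mm=geometry.pixel_spacing_mm,
        )

    covar_cols = ["sex", "age", "age_band", "heart_rate", "systolic_bp", "diastolic_bp"]
    seg_rows, qc_rows = [], []
    subject_seeds = seed_subjects.spawn(len(subjects))
    for subject, sseq in zip(subjects, subject_seeds):
        slice_seeds = sseq.spawn(len(SLICES))
        for sl, slseq in zip(SLICES, slice_seeds):
            truth = render_ground_truth(subject, geometry, sl)
            rng = np.random.default_rng(slseq)
            artifact_here = (
                config.artifact is not None
                and rng.random() < config.artifact.probability
            )
            for kind in MAP_KINDS:
                series = _simulate_series(
                    subject, truth, geometry, kind, config, rng
                )
                if artifact_here:
                    spec = replace(config.artifact, slice=sl, probability=1.0)
                    series, _ = inject_artifact(
                        series, spec, truth.labels, geometry,
                        seed=int(rng.integers(2**31)),
                    )
                if config.motion_sd_px > 0:
                    shifts = random_shifts(
                        len(series.frames), config.motion_sd_px, rng
                    )
                    series, _ = apply_motion(series, shifts)
                shift_log = None
                if config.register:
                    series, shift_log = register_series(series, mask=rois[sl])
                if kind == "t2":
                    pmap = fit_t2_map(series, rois[sl], config.fit_options)
                else:
                    pmap = fit_t1_map(series, rois[sl], config.fit_options)
                flags = flag_artifact_pixels(pmap, thresholds)
                report = segment_eligibility(
                    flags, segmasks[sl], shift_log, series, thresholds,
                    map_kind=kind, subject_id=subject.subject_id,
                )
                qc_rows.append(report)
                stats_df = segment_statistics(pmap, segmasks[sl])
                merged = stats_df.merge(
                    report[["segment", "eligible", "reason"]], on="segment"
                )
                merged["value"] = merged["mean"]
                for c in covar_cols:
                    merged[c] = getattr(subject, c)
                merged["observer"] = "O1"
                merged["replicate"] = 1
                seg_rows.append(merged)

    segment_table = pd.concat(seg_rows, ignore_index=True)
    qc_reports = pd.concat(qc_rows, ignore_index=True)
    qc_summary = summarize_qc(qc_reports)

    from .stats import COFACTORS

    cofs = tuple(COFACTORS) if cofactors is None else cofactors
    models: dict[str, ModelResult] = {}
    bullseye_rows = []
    for kind in MAP_KINDS:
        models[kind] = fit_reference_model(
            segment_table, kind, unit="slice", cofactors=cofs
        )
        if bullseye_models:
            seg_model = fit_reference_model(
                segment_table, kind, unit="segment", cofactors=cofs
            )
            be = seg_model.ls_means.copy()
            be["map_kind"] = kind
            bullseye_rows.append(be)
    bullseye = (
        pd.concat(bullseye_rows, ignore_index=True)
        if bullseye_rows
        else pd.DataFrame()
    )

    reference_table = _reference_table(segment_table, models)
    agreement = _observer_agreement(
        segment_table, observer_subjects, seed_observer
    )
    hr_split = None
    if config.cohort.hr_effect:
        hr_split = {
            kind: cofactor_split_means(segment_table, kind, "heart_rate")
            for kind in config.cohort.hr_effect
        }

    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_subjects": len(subjects),
    }
    return ReportBundle(
        cofactor_corr=cofactor_correlations(cohort_table(subjects)),
        cohort=cohort_table(subjects),
        segment_table=segment_table,
        qc_reports=qc_reports,
        qc_summary=qc_summary,
        models=models,
        reference_table=reference_table,
        bullseye=bullseye,
        agreement=agreement,
        hr_split=hr_split,
        provenance=provenance,
    )


def _simulate_series(subject, truth, geometry, kind, config, rng):
    seed = int(rng.integers(2**31))
    if kind == "t2":
        return simulate_t2prep_series(
            truth, geometry, config.noise_sd, seed,
            subject_id=subject.subject_id, rr_interval_ms=subject.rr_interval,
        )
    regime = "pre" if kind == "t1_pre" else "post"
    return simulate_molli_series(
        truth, geometry, regime, subject.rr_interval,
        ba_ratio=config.ba_ratio, noise_sd=config.noise_sd, seed=seed,
        subject_id=subject.subject_id,
    )


def _reference_table(segment_table: pd.DataFrame, models: dict) -> pd.DataFrame:
    """Per-slice LS means, tolerance intervals and observed min-max."""
    eligible = segment_table[segment_table["eligible"]]
    slice_means = slice_statistics(eligible)
    rows = []
    for kind, model in models.items():
        obs = slice_means[slice_means["map_kind"] == kind]
        for _, r in model.ls_means.iterrows():
            sl = r["slice"]
            vals = obs.loc[obs["slice"] == sl, "mean"]
            rows.append(
                {
                    "map_kind": kind,
                    "slice": sl,
                    "ls_mean": r["mean"],
                    "tol_lower": r["tol_lower"],
                    "tol_upper": r["tol_upper"],
                    "min": vals.min() if len(vals) else np.nan,
                    "max": vals.max() if len(vals) else np.nan,
                    "scatter_factor": model.scatter_total,
                }
            )
    return pd.DataFrame(rows)


def _observer_agreement(segment_table, n_subjects, seed_seq) -> dict:
    """Simulated repeat reading of T2 and pre-contrast T1 segments.

    A random subject subset is re-measured twice (intra) and by a second
    reader (inter) with packaged perturbation settings; Bland-Altman and
    Pearson statistics are computed on the replicate pairs.
    """
    settings = load_observer_settings()
    rng = np.random.default_rng(seed_seq)
    out: dict = {}
    for kind in ("t2", "t1_pre"):
        df = segment_table[
            (segment_table["map_kind"] == kind) & segment_table["eligible"]
        ]
        subjects = df["subject_id"].unique()
        chosen = rng.choice(
            subjects, size=min(n_subjects, len(subjects)), replace=False
        )
        base = df[df["subject_id"].isin(chosen)]
        out[kind] = {}
        for mode, observers in (("intra", ("O1", "O1")), ("inter", ("O1", "O2"))):
            cfg = settings[kind][mode]
            sd_rep = cfg["sd_diff"] / np.sqrt(2.0)
            dup = simulate_observer_remeasurement(
                base, sd_rep, bias=cfg["bias"],
                seed=int(rng.integers(2**31)), observers=observers,
            )
            rep1 = dup[dup["replicate"] == 1]["value"].to_numpy()
            rep2 = dup[dup["replicate"] == 2]["value"].to_numpy()
            out[kind][mode] = bland_altman(rep1, rep2)
    return out


def write_report_bundle(bundle: ReportBundle, out_dir) -> Path:
    """Persist a report bundle as CSV/JSON files with provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.cohort.to_csv(out / "cohort.csv", index=False)
    bundle.segment_table.to_csv(out / "segment_table.csv", index=False)
    bundle.qc_reports.to_csv(out / "qc_reports.csv", index=False)
    bundle.reference_table.to_csv(out / "reference_table.csv", index=False)
    if bundle.cofactor_corr is not None:
        bundle.cofactor_corr.to_csv(out / "cofactor_correlations.csv")
    if len(bundle.bullseye):
        bundle.bullseye.to_csv(out / "bullseye.csv", index=False)
    model_summary = {
        kind: {
            "ls_means": m.ls_means.to_dict(orient="records"),
            "sigma2_subject": m.sigma2_subject,
            "sigma2_resid": m.sigma2_resid,
            "scatter_total": m.scatter_total,
            "scatter_subject": m.scatter_subject,
            "retained_cofactors": m.retained_cofactors,
            "cofactor_pvalues": m.cofactor_pvalues,
            "elimination_trace": m.elimination_trace,
            "hr_split": m.hr_split,
            "n_subjects": m.n_subjects,
        }
        for kind, m in bundle.models.items()
    }
    agreement = {
        kind: {mode: vars(res) for mode, res in modes.items()}
        for kind, modes in bundle.agreement.items()
    }
    payload = {
        "provenance": bundle.provenance,
        "qc_summary": bundle.qc_summary,
        "models": model_summary,
        "agreement": agreement,
    }
    if bundle.hr_split:
        payload["hr_split"] = {
            kind: {
                "split": res["split"],
                "below": res["below"].to_dict(orient="records"),
                "above": res["above"].to_dict(orient="records"),
            }
            for kind, res in bundle.hr_split.items()
        }
    (out / "report.json").write_text(json.dumps(payload, indent=1, default=float))
    return out
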