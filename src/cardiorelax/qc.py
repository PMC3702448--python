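"""Automated quality control: rule-based proxies for visual reading.

Visual consensus quality assessment is replaced by deterministic rules:

* pixel level — a fitted pixel is flagged when it did not converge,
  violated the physiologic clamp range, or its residual RMSE exceeds a
  multiple of the slice-median RMSE (susceptibility proxy);
* segment level — a segment is excluded when its artifact-pixel fraction
  exceeds a threshold (reason ``susceptibility``), when any frame of its
  series failed registration (reason ``motion``), or when the series
  timing is inconsistent with the recorded RR interval (reason
  ``mistrigger``).  Reason precedence: mistrigger > motion > susceptibility.

Excluded segments never contribute to downstream statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import QCThresholds
from .phantom import SEGMENT_IDS, ImageSeries, molli_inversion_times
from .registration import ShiftEstimate
from .relaxometry import ParameterMap

__all__ = [
    "flag_artifact_pixels",
    "timing_is_mistriggered",
    "segment_eligibility",
    "summarize_qc",
    "REASONS",
]

REASONS = ("none", "susceptibility", "motion", "mistrigger")


def flag_artifact_pixels(
    pmap: ParameterMap, thresholds: QCThresholds | None = None
) -> np.ndarray:
    """Boolean mask of suspect pixels within the fitted ROI."""
    thresholds = thresholds or QCThresholds()
    mask = pmap.mask
    flags = np.zeros(mask.shape, dtype=bool)
    flags[mask] = ~pmap.converged[mask]
    finite_rmse = pmap.rmse[mask & np.isfinite(pmap.rmse)]
    if finite_rmse.size:
        median = np.median(finite_rmse)
        if median > 0:
            high = pmap.rmse > thresholds.rmse_multiplier * median
            flags |= mask & np.nan_to_num(high, nan=False)
    return flags


def timing_is_mistriggered(
    series: ImageSeries, thresholds: QCThresholds | None = None
) -> bool:
    """Check the series timing against its recorded RR interval.

    MOLLI frames must sit on the 3-3-5 RR-spaced grid implied by the
    recorded RR interval within the tolerance; a series without RR
    metadata cannot be checked and passes.
    """
    thresholds = thresholds or QCThresholds()
    if series.kind == "t2prep" or series.rr_interval_ms is None:
        return False
    expected = molli_inversion_times(series.rr_interval_ms)
    dev = np.abs(series.timings_ms - expected)
    return bool(np.any(dev > thresholds.mistrigger_tolerance_ms))


def segment_eligibility(
    flags: np.ndarray,
    segmask: np.ndarray,
    shift_log: ShiftEstimate | None = None,
    series: ImageSeries | None = None,
    thresholds: QCThresholds | None = None,
    map_kind: str = "",
    subject_id: str = "",
) -> pd.DataFrame:
    """Per-segment QC report for one subject-slice-map.

    Columns: subject_id, map_kind, slice, segment, eligible, reason,
    artifact_fraction.
    """
    thresholds = thresholds or QCThresholds()
    segmask = np.asarray(segmask)
    if flags.shape != segmask.shape:
        raise ValueError("flag mask and segment mask must align")
    present = sorted(set(np.unique(segmask)) - {0})
    if not present:
        raise ValueError("segment mask is empty")
    slice_name = next(
        sl for sl, ids in SEGMENT_IDS.items() if set(present) <= set(ids)
    )
    mistrigger = (
        series is not None
        and timing_is_mistriggered(series, thresholds)
    )
    motion = (
        thresholds.propagate_registration
        and shift_log is not None
        and bool(shift_log.failed.any())
    )
    rows = []
    for seg in present:
        sel = segmask == seg
        frac = float(flags[sel].mean()) if sel.any() else 0.0
        if mistrigger:
            reason = "mistrigger"
        elif motion:
            reason = "motion"
        elif frac > thresholds.max_artifact_fraction:
            reason = "susceptibility"
        else:
            reason = "none"
        rows.append(
            {
                "subject_id": subject_id,
                "map_kind": map_kind,
                "slice": slice_name,
                "segment": seg,
                "eligible": reason == "none",
                "reason": reason,
                "artifact_fraction": frac,
            }
        )
    return pd.DataFrame(rows)


def summarize_qc(reports: pd.DataFrame) -> dict:
    """Cohort-level eligibility summary per map kind.

    Returns, per map kind: segment counts and fractions by reason and the
    fraction of subjects with at least one excluded segment.  Fractions by
    reason (including ``none``) sum to 1.
    """
    if reports.empty:
        raise ValueError("no QC reports")
    out: dict = {}
    for kind, df in reports.groupby("map_kind", sort=False):
        n = len(df)
        counts = {r: int((df["reason"] == r).sum()) for r in REASONS}
        fractions = {r: counts[r] / n for r in REASONS}
        per_subject = df.groupby("subject_id")["eligible"].agg(
            lambda s: bool((~s).any())
        )
        out[kind] = {
            "n_segments": n,
            "n_eligible": counts["none"],
            "fraction_eligible": fractions["none"],
            "counts": counts,
            "fractions": fractions,
            "subjects_with_exclusion": int(per_subject.sum()),
            "fraction_subjects_with_exclusion": float(per_subject.mean()),
        }
    return out
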