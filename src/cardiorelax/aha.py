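"""Myocardial ROI delineation and AHA 16-segment quantification.

The left-ventricular myocardium of a short-axis slice is an annulus between
an endocardial and an epicardial contour.  Contours are eroded inward from
both borders (default 15% of the wall thickness each side) to emulate
conservative mid-wall contouring that leaves out the trabeculated layer and
the epicardial border.  The ROI is partitioned into AHA segments: six
60-degree sectors per basal/mid slice (ids 1-6 / 7-12), four 90-degree
sectors apically (ids 13-16), anchored at the anterior RV insertion angle.
No apical-cap segment 17 is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PhantomGeometry, SLICES
from .phantom import SEGMENT_IDS, _pixel_grid, _sector_labels
from .relaxometry import ParameterMap

__all__ = [
    "Contours",
    "contours_from_truth",
    "roi_mask_from_contours",
    "aha_segment_mask",
    "segment_statistics",
    "slice_statistics",
]


@dataclass(frozen=True)
class Contours:
    """Closed endo-/epicardial polygons in pixel coordinates (row, col)."""

    endocardium: np.ndarray       # (n, 2)
    epicardium: np.ndarray        # (n, 2)
    slice: str
    rv_insertion_angle: float
    #: radii in mm retained for mask rasterisation of circular contours
    endo_radius_mm: float = None
    epi_radius_mm: float = None


def contours_from_truth(
    geometry: PhantomGeometry, slice_name: str, erosion_fraction: float = 0.15
) -> Contours:
    """Mid-wall contours from phantom geometry.

    The endocardial contour is pushed outward and the epicardial contour
    inward by ``erosion_fraction`` of the wall thickness each, discretised
    at 1-degree steps.
    """
    if not 0 <= erosion_fraction < 0.5:
        raise ValueError("erosion fraction must be in [0, 0.5)")
    if slice_name not in SLICES:
        raise ValueError(f"unknown slice {slice_name!r}")
    geometry.validate()
    endo, epi = geometry.radii_mm[slice_name]
    wall = epi - endo
    r_in = endo + erosion_fraction * wall
    r_out = epi - erosion_fraction * wall
    if (r_out - r_in) < geometry.pixel_spacing_mm:
        raise ValueError("erosion leaves less than one pixel of wall")
    n = geometry.grid_size
    c = (n - 1) / 2.0
    ang = np.deg2rad(np.arange(360.0))
    sp = geometry.pixel_spacing_mm

    def circle(radius_mm):
        x = radius_mm * np.cos(ang) / sp
        y = radius_mm * np.sin(ang) / sp
        return np.column_stack([c - y, c + x])   # (row, col), +y up

    return Contours(
        endocardium=circle(r_in),
        epicardium=circle(r_out),
        slice=slice_name,
        rv_insertion_angle=geometry.rv_insertion_angle,
        endo_radius_mm=r_in,
        epi_radius_mm=r_out,
    )


def roi_mask_from_contours(
    contours: Contours, geometry: PhantomGeometry
) -> np.ndarray:
    """Rasterise the annular ROI between the two contours."""
    r, _ = _pixel_grid(geometry)
    return (r >= contours.endo_radius_mm) & (r < contours.epi_radius_mm)


def aha_segment_mask(
    roi: np.ndarray,
    rv_insertion_angle: float,
    slice_name: str,
    centroid: tuple[float, float] | None = None,
    pixel_spacing_mm: float = 1.0,
) -> np.ndarray:
    """Partition an ROI mask into AHA sectors around its centroid.

    ``centroid`` is (row, col); defaults to the ROI centroid.  Returns an
    integer label map, 0 outside the ROI.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    if slice_name not in SLICES:
        raise ValueError(f"unknown slice {slice_name!r}")
    h, w = roi.shape
    if centroid is None:
        rows, cols = np.nonzero(roi)
        centroid = (rows.mean(), cols.mean())
    if not (0 <= centroid[0] < h and 0 <= centroid[1] < w):
        raise ValueError("centroid outside the grid")
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - centroid[1]
    y = centroid[0] - rows                     # +y up
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    labels = np.zeros(roi.shape, dtype=int)
    labels[roi] = _sector_labels(theta, slice_name, rv_insertion_angle)[roi]
    return labels


def segment_statistics(pmap: ParameterMap, segmask: np.ndarray) -> pd.DataFrame:
    """Per-segment mean/median/SD of a fitted map, NaN pixels excluded.

    ``n_pixels`` counts finite (converged) pixels; ``n_total`` all ROI
    pixels of the segment.  Statistics are NaN iff ``n_pixels`` is 0.
    """
    segmask = np.asarray(segmask)
    if segmask.shape != pmap.values.shape:
        raise ValueError("segment mask shape must match the map")
    slice_name = pmap.slice or _slice_of_labels(segmask)
    rows = []
    for seg in SEGMENT_IDS[slice_name]:
        sel = segmask == seg
        vals = pmap.values[sel]
        finite = vals[np.isfinite(vals)]
        rows.append(
            {
                "segment": seg,
                "slice": slice_name,
                "map_kind": pmap.kind,
                "subject_id": pmap.subject_id,
                "mean": finite.mean() if finite.size else np.nan,
                "median": float(np.median(finite)) if finite.size else np.nan,
                "sd": finite.std(ddof=1) if finite.size > 1 else (0.0 if finite.size else np.nan),
                "n_pixels": int(finite.size),
                "n_total": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def slice_statistics(stats: pd.DataFrame) -> pd.DataFrame:
    """Pixel-count-weighted per-slice means of segment statistics."""
    def agg(df):
        w = df["n_pixels"].to_numpy(dtype=float)
        m = df["mean"].to_numpy(dtype=float)
        ok = (w > 0) & np.isfinite(m)
        return pd.Series(
            {
                "mean": float(np.average(m[ok], weights=w[ok])) if ok.any() else np.nan,
                "n_pixels": int(w[ok].sum()),
            }
        )

    return (
        stats.groupby(["subject_id", "map_kind", "slice"], sort=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )


def _slice_of_labels(segmask: np.ndarray) -> str:
    present = set(np.unique(segmask)) - {0}
    for sl, ids in SEGMENT_IDS.items():
        if present <= set(ids):
            return sl
    raise ValueError("segment ids do not belong to a single slice level")
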