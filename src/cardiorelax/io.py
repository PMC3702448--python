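"""NIfTI-1 + JSON-sidecar persistence for series, maps and masks.

An :class:`~cardiorelax.phantom.ImageSeries` is stored as one NIfTI file
with frames on the 4th axis plus a ``.json`` sidecar holding
``{kind, timings_ms, slice, subject_id, pixel_spacing_mm, rr_interval_ms}``.
Parameter maps are stored with the primary map and companion layers on the
4th axis, documented in the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import FitOptions
from .phantom import ImageSeries
from .relaxometry import ParameterMap

__all__ = [
    "write_series",
    "read_series",
    "write_map",
    "read_map",
    "write_label_map",
    "read_label_map",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(spacing: float) -> np.ndarray:
    return np.diag([spacing, spacing, 1.0, 1.0])


def write_series(series: ImageSeries, path) -> Path:
    """Write a series as NIfTI (H x W x 1 x frames) with a JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(series.frames, 0, -1)[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float32), _affine(series.pixel_spacing_mm))
    nib.save(img, path)
    sidecar = {
        "kind": series.kind,
        "timings_ms": [float(t) for t in series.timings_ms],
        "slice": series.slice,
        "subject_id": series.subject_id,
        "pixel_spacing_mm": series.pixel_spacing_mm,
        "rr_interval_ms": series.rr_interval_ms,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path) -> ImageSeries:
    """Read a series written by :func:`write_series`."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.asarray(nib.load(path).dataobj, dtype=float)
    frames = np.moveaxis(data[:, :, 0, :], -1, 0)
    return ImageSeries(
        frames=frames,
        timings_ms=np.asarray(meta["timings_ms"], dtype=float),
        kind=meta["kind"],
        slice=meta["slice"],
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
        subject_id=meta.get("subject_id", ""),
        rr_interval_ms=meta.get("rr_interval_ms"),
    )


_MAP_LAYERS = ("values", "amplitude", "rmse", "converged", "mask")
_T1_LAYERS = _MAP_LAYERS + ("amplitude_b", "t1_star", "polarity_index")


def write_map(pmap: ParameterMap, path, pixel_spacing_mm: float = 1.0) -> Path:
    """Write a parameter map and its companion layers (4th axis)."""
    path = Path(path)
    layers = _T1_LAYERS if pmap.kind != "t2" else _MAP_LAYERS
    stack = np.stack(
        [np.asarray(getattr(pmap, layer), dtype=float) for layer in layers], axis=-1
    )[:, :, None, :]
    img = nib.Nifti1Image(stack.astype(np.float32), _affine(pixel_spacing_mm))
    nib.save(img, path)
    sidecar = {
        "kind": pmap.kind,
        "units": "ms",
        "slice": pmap.slice,
        "subject_id": pmap.subject_id,
        "layers": list(layers),
        "fit_options": pmap.fit_options.__dict__ if pmap.fit_options else {},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=list))
    return path


def read_map(path) -> ParameterMap:
    """Read a parameter map written by :func:`write_map`."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.asarray(nib.load(path).dataobj, dtype=float)[:, :, 0, :]
    layers = dict(zip(meta["layers"], np.moveaxis(data, -1, 0)))
    fo = meta.get("fit_options") or {}
    for key in ("t2_clamp_ms", "t1_clamp_ms", "t2_search_ms", "t1_star_search_ms"):
        if key in fo:
            fo[key] = tuple(fo[key])
    return ParameterMap(
        values=layers["values"],
        amplitude=layers["amplitude"],
        rmse=layers["rmse"],
        converged=layers["converged"].astype(bool),
        mask=layers["mask"].astype(bool),
        kind=meta["kind"],
        slice=meta.get("slice", ""),
        subject_id=meta.get("subject_id", ""),
        amplitude_b=layers.get("amplitude_b"),
        t1_star=layers.get("t1_star"),
        polarity_index=(
            layers["polarity_index"].astype(int)
            if "polarity_index" in layers
            else None
        ),
        fit_options=FitOptions(**fo) if fo else FitOptions(),
    )


def write_label_map(labels: np.ndarray, path, pixel_spacing_mm: float = 1.0) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(labels, dtype=np.int16)[:, :, None], _affine(pixel_spacing_mm)
    )
    nib.save(img, path)
    return path


def read_label_map(path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj, dtype=int)[:, :, 0]
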