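"""Digital short-axis phantom: cohort simulation and image-series synthesis.

The phantom emulates the data the analysis assumes: for each simulated
volunteer, three short-axis slices of an annular left-ventricular
myocardium, each imaged with a three-point T2-prepared series (preparation
times 0/24/55 ms) and eleven-frame MOLLI inversion-recovery series (3-3-5
pattern, RR-spaced inversion times) before and after contrast.  Ground-truth
relaxation times are drawn log-normally around configured per-slice
geometric means with a subject-level multiplicative scatter factor, plus
optional heart-rate and age effects applied on the log scale.

Magnitude images carry Rician noise (magnitude of a complex Gaussian
perturbation); inferolateral susceptibility artifacts and inter-frame
translations can be injected with their ground truth returned for QC and
registration validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    BLOOD_VALUES,
    MAP_KINDS,
    MOLLI_BASE_TI_MS,
    MOLLI_GROUP_SIZES,
    SLICES,
    T2PREP_TIMES_MS,
    TISSUE_S0,
    ArtifactSpec,
    CohortConfig,
    ConfigurationError,
    PhantomGeometry,
)

__all__ = [
    "SubjectRecord",
    "ImageSeries",
    "SliceTruth",
    "build_cohort",
    "render_ground_truth",
    "simulate_t2prep_series",
    "simulate_molli_series",
    "molli_inversion_times",
    "inject_artifact",
    "apply_motion",
    "random_shifts",
    "simulate_observer_remeasurement",
    "segment_slice",
    "SEGMENT_IDS",
]

#: AHA segment ids per slice level (no apical cap; 16-segment model)
SEGMENT_IDS = {
    "base": tuple(range(1, 7)),
    "middle": tuple(range(7, 13)),
    "apex": tuple(range(13, 17)),
}


def segment_slice(segment_id: int) -> str:
    """Slice level an AHA segment id belongs to."""
    if 1 <= segment_id <= 6:
        return "base"
    if 7 <= segment_id <= 12:
        return "middle"
    if 13 <= segment_id <= 16:
        return "apex"
    raise ValueError(f"invalid AHA segment id {segment_id}")


class TimingError(ValueError):
    """MOLLI timing scheme inconsistent with the RR interval."""


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated volunteer: covariates plus per-segment ground truth."""

    subject_id: str
    sex: str                      # "M" | "F"
    age: float                    # years
    age_band: str                 # "20-39" | "40-59" | "60-80"
    heart_rate: float             # min^-1
    systolic_bp: float            # mmHg
    diastolic_bp: float           # mmHg
    #: map kind -> {segment id -> true value, ms}
    truth: dict = field(repr=False, default_factory=dict)

    @property
    def rr_interval(self) -> float:
        """RR interval in ms, consistent with heart rate by construction."""
        return 60000.0 / self.heart_rate

    def segment_truth(self, map_kind: str, segment_id: int) -> float:
        return self.truth[map_kind][segment_id]


@dataclass
class ImageSeries:
    """Ordered stack of 2-D magnitude frames with per-frame timing.

    ``timings_ms`` holds T2-preparation times for ``kind='t2prep'`` and
    inversion times for the MOLLI kinds.  Frames of a MOLLI series are
    sorted by inversion time.
    """

    frames: np.ndarray            # (n_frames, H, W), magnitude, >= 0
    timings_ms: np.ndarray       # (n_frames,)
    kind: str                    # "t2prep" | "molli_pre" | "molli_post"
    slice: str
    pixel_spacing_mm: float
    subject_id: str = ""
    rr_interval_ms: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.timings_ms = np.asarray(self.timings_ms, dtype=float)
        if self.frames.ndim != 3 or len(self.frames) != len(self.timings_ms):
            raise ValueError("frames/timing mismatch")
        if self.kind == "t2prep":
            if len(self.frames) != 3 or not np.allclose(
                self.timings_ms, T2PREP_TIMES_MS
            ):
                raise ValueError("t2prep series must have timings (0, 24, 55) ms")
        elif self.kind in ("molli_pre", "molli_post"):
            if len(self.frames) != 11:
                raise ValueError("MOLLI series must have 11 frames")
            if not np.all(np.diff(self.timings_ms) > 0):
                raise ValueError("MOLLI inversion times must be strictly increasing")
        else:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if np.any(self.frames < 0):
            raise ValueError("magnitude frames must be non-negative")

    def copy_with(self, **kw) -> "ImageSeries":
        out = ImageSeries(
            frames=kw.pop("frames", self.frames.copy()),
            timings_ms=kw.pop("timings_ms", self.timings_ms.copy()),
            kind=kw.pop("kind", self.kind),
            slice=kw.pop("slice", self.slice),
            pixel_spacing_mm=kw.pop("pixel_spacing_mm", self.pixel_spacing_mm),
            subject_id=kw.pop("subject_id", self.subject_id),
            rr_interval_ms=kw.pop("rr_interval_ms", self.rr_interval_ms),
        )
        if kw:
            raise TypeError(f"unknown fields {sorted(kw)}")
        return out


@dataclass
class SliceTruth:
    """Rasterised ground truth of one slice."""

    labels: np.ndarray            # (H, W) int, AHA ids, 0 outside myocardium
    maps: dict                    # map kind -> (H, W) true values, ms
    s0: np.ndarray                # (H, W) proton-density scale
    slice: str


# ---------------------------------------------------------------------------
# cohort


def _band_label(band: tuple[float, float]) -> str:
    return f"{band[0]:.0f}-{band[1]:.0f}"


def build_cohort(config: CohortConfig, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a cohort of :class:`SubjectRecord` from ``config``.

    Subjects are allocated to the six sex x age-band strata either
    ``n_per_stratum`` each or, when ``config.n_total`` is given, round-robin
    so stratum sizes differ by at most one.  Per-subject truths are the
    per-slice reference values times a subject-level log-normal factor
    ``scatter^z`` (z ~ N(0,1)), times the heart-rate / age shifts where the
    subject qualifies.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    bands = sorted(config.age_bands)
    strata = [(sex, b) for b in bands for sex in ("M", "F")]
    if config.n_total is not None:
        counts = [config.n_total // 6 + (1 if i < config.n_total % 6 else 0)
                  for i in range(6)]
    else:
        counts = [config.n_per_stratum] * 6

    hr_dist = config.heart_rate
    bp = config.blood_pressure
    # first pass: covariates for every subject
    covariates = []
    idx = 0
    for (sex, band), count in zip(strata, counts):
        for _ in range(count):
            idx += 1
            age = rng.uniform(band[0], band[1] + 1.0)
            # truncated normal heart rate within the admissible range
            while True:
                hr = rng.normal(hr_dist.mean, hr_dist.sd)
                if hr_dist.min <= hr <= hr_dist.max:
                    break
            sys_bp = rng.normal(bp.systolic_mean, bp.systolic_sd)
            dia_bp = rng.normal(bp.diastolic_mean, bp.diastolic_sd)
            covariates.append((f"S{idx:03d}", sex, band, age, hr, sys_bp, dia_bp))
    # the heart-rate effect applies above the cohort's own median
    hr_median = float(np.median([c[4] for c in covariates]))

    subjects: list[SubjectRecord] = []
    for subject_id, sex, band, age, hr, sys_bp, dia_bp in covariates:
        truth: dict = {}
        for kind in MAP_KINDS:
            if kind not in config.reference_values:
                continue
            z = rng.standard_normal()
            sf = config.scatter_factors.get(kind, 1.0)
            factor = math.exp(z * math.log(sf))
            per_seg = {}
            for sl in SLICES:
                value = config.reference_values[kind][sl] * factor
                if (
                    config.hr_effect
                    and kind in config.hr_effect
                    and hr > hr_median
                ):
                    value *= config.hr_effect[kind][sl]
                if (
                    kind == "t1_pre"
                    and config.age_effect_t1_pre is not None
                    and band == bands[-1]
                ):
                    value *= config.age_effect_t1_pre
                for seg in SEGMENT_IDS[sl]:
                    per_seg[seg] = value
            truth[kind] = per_seg
        subjects.append(
            SubjectRecord(
                subject_id=subject_id,
                sex=sex,
                age=float(age),
                age_band=_band_label(band),
                heart_rate=float(hr),
                systolic_bp=float(sys_bp),
                diastolic_bp=float(dia_bp),
                truth=truth,
            )
        )
    return subjects


def cohort_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Covariate table of a cohort (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": [s.sex for s in subjects],
            "age": [s.age for s in subjects],
            "age_band": [s.age_band for s in subjects],
            "heart_rate": [s.heart_rate for s in subjects],
            "systolic_bp": [s.systolic_bp for s in subjects],
            "diastolic_bp": [s.diastolic_bp for s in subjects],
            "rr_interval": [s.rr_interval for s in subjects],
        }
    )


# ---------------------------------------------------------------------------
# geometry rasterisation


def _pixel_grid(geometry: PhantomGeometry):
    """Radius (mm) and angle (deg CCW from +x, y up) of every pixel centre."""
    n = geometry.grid_size
    c = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    x = (cols - c) * geometry.pixel_spacing_mm
    y = (c - rows) * geometry.pixel_spacing_mm   # +y up
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return r, theta


def _sector_labels(theta: np.ndarray, slice_name: str, rv_angle: float) -> np.ndarray:
    """AHA sector id for every pixel angle (annulus masking applied later).

    Basal/mid rings: six 60-degree sectors numbered counter-clockwise
    anterior(1) -> anteroseptal(2) -> inferoseptal(3) -> inferior(4) ->
    inferolateral(5) -> anterolateral(6); the anterior RV insertion is the
    boundary between the anterior and anteroseptal sectors.  Apical ring:
    four 90-degree sectors anterior(13), septal(14), inferior(15),
    lateral(16) sharing the anterior direction with the basal ring.
    """
    if slice_name in ("base", "middle"):
        order = np.array([2, 3, 4, 5, 6, 1])
        offset = np.floor(((theta - rv_angle) % 360.0) / 60.0).astype(int)
        labels = order[np.clip(offset, 0, 5)]
        if slice_name == "middle":
            labels = labels + 6
    else:
        anterior = rv_angle - 30.0
        offset = np.floor(((theta - (anterior - 45.0)) % 360.0) / 90.0).astype(int)
        labels = np.array([13, 14, 15, 16])[np.clip(offset, 0, 3)]
    return labels


def render_ground_truth(
    subject: SubjectRecord, geometry: PhantomGeometry, slice_name: str
) -> SliceTruth:
    """Rasterise one slice: AHA label map, true parameter maps, S0 map.

    Myocardial pixels carry their segment's ground truth; the blood pool
    carries fixed values (T1 above myocardium pre-contrast, below it
    post-contrast); the background has zero proton density.
    """
    if slice_name not in SLICES:
        raise ValueError(f"unknown slice {slice_name!r}")
    geometry.validate()
    endo, epi = geometry.radii_mm[slice_name]
    r, theta = _pixel_grid(geometry)
    annulus = (r >= endo) & (r < epi)
    blood = r < endo
    labels = np.zeros(r.shape, dtype=int)
    labels[annulus] = _sector_labels(theta, slice_name, geometry.rv_insertion_angle)[
        annulus
    ]
    s0 = np.zeros(r.shape)
    s0[annulus | blood] = TISSUE_S0
    maps = {}
    for kind in MAP_KINDS:
        if kind not in subject.truth:
            continue
        m = np.full(r.shape, 1.0)    # background value irrelevant (S0 = 0)
        m[blood] = BLOOD_VALUES[kind]
        for seg in SEGMENT_IDS[slice_name]:
            m[labels == seg] = subject.segment_truth(kind, seg)
        maps[kind] = m
    return SliceTruth(labels=labels, maps=maps, s0=s0, slice=slice_name)


# ---------------------------------------------------------------------------
# signal synthesis


def _rician(signal: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise), sigma per channel."""
    if noise_sd == 0:
        return np.abs(signal)
    re = signal + rng.normal(0.0, noise_sd, signal.shape)
    im = rng.normal(0.0, noise_sd, signal.shape)
    return np.hypot(re, im)


def simulate_t2prep_series(
    truth: SliceTruth,
    geometry: PhantomGeometry,
    noise_sd: float = 1.0,
    seed: int | None = None,
    subject_id: str = "",
    rr_interval_ms: float | None = None,
) -> ImageSeries:
    """T2-prepared series: S(TE) = S0 exp(-TE/T2) at TE = 0, 24, 55 ms."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if "t2" not in truth.maps:
        raise ValueError("truth is missing a T2 map")
    rng = np.random.default_rng(seed)
    t2 = truth.maps["t2"]
    frames = [
        _rician(truth.s0 * np.exp(-te / t2), noise_sd, rng) for te in T2PREP_TIMES_MS
    ]
    return ImageSeries(
        frames=np.stack(frames),
        timings_ms=np.array(T2PREP_TIMES_MS),
        kind="t2prep",
        slice=truth.slice,
        pixel_spacing_mm=geometry.pixel_spacing_mm,
        subject_id=subject_id,
        rr_interval_ms=rr_interval_ms,
    )


def molli_inversion_times(rr_interval_ms: float) -> np.ndarray:
    """Effective inversion times of the 3-3-5 MOLLI scheme, sorted.

    Group g has base TI ``MOLLI_BASE_TI_MS[g]`` and contributes
    ``base + k * RR`` for k = 0..n_g-1 with group sizes (3, 3, 5).
    """
    if rr_interval_ms <= 0:
        raise TimingError("rr_interval must be positive")
    span = max(MOLLI_BASE_TI_MS) - min(MOLLI_BASE_TI_MS)
    if rr_interval_ms <= span:
        raise TimingError(
            f"RR interval {rr_interval_ms:.0f} ms overlaps the Look-Locker "
            f"groups (base TIs span {span:.0f} ms)"
        )
    tis = [
        base + k * rr_interval_ms
        for base, n in zip(MOLLI_BASE_TI_MS, MOLLI_GROUP_SIZES)
        for k in range(n)
    ]
    return np.sort(np.array(tis))


def simulate_molli_series(
    truth: SliceTruth,
    geometry: PhantomGeometry,
    regime: str,
    rr_interval_ms: float,
    ba_ratio: float = 2.2,
    noise_sd: float = 1.0,
    seed: int | None = None,
    subject_id: str = "",
) -> ImageSeries:
    """MOLLI magnitude series |A - B exp(-TI/T1*)| with Rician noise.

    A is the proton-density scale, B = ba_ratio * A and
    T1* = T1 / (ba_ratio - 1), so the Look-Locker correction
    T1 = T1* (B/A - 1) returns the true T1 exactly.
    """
    if regime not in ("pre", "post"):
        raise ValueError("regime must be 'pre' or 'post'")
    if ba_ratio <= 1:
        raise ValueError("ba_ratio must exceed 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    kind = "t1_pre" if regime == "pre" else "t1_post"
    if kind not in truth.maps:
        raise ValueError(f"truth is missing a {kind} map")
    rng = np.random.default_rng(seed)
    tis = molli_inversion_times(rr_interval_ms)
    t1 = truth.maps[kind]
    t1_star = t1 / (ba_ratio - 1.0)
    a = truth.s0
    frames = [
        _rician(a * (1.0 - ba_ratio * np.exp(-ti / t1_star)), noise_sd, rng)
        for ti in tis
    ]
    return ImageSeries(
        frames=np.stack(frames),
        timings_ms=tis,
        kind=f"molli_{regime}",
        slice=truth.slice,
        pixel_spacing_mm=geometry.pixel_spacing_mm,
        subject_id=subject_id,
        rr_interval_ms=rr_interval_ms,
    )


# ---------------------------------------------------------------------------
# artifacts and motion


def artifact_mask(
    spec: ArtifactSpec, labels: np.ndarray, geometry: PhantomGeometry
) -> np.ndarray:
    """Boolean mask of annulus pixels inside the artifact sector."""
    spec.validate()
    r, theta = _pixel_grid(geometry)
    annulus = labels > 0
    half = spec.angular_extent / 2.0
    dang = np.abs((theta - spec.center_angle + 180.0) % 360.0 - 180.0)
    mask = annulus & (dang <= half)
    if spec.radial_extent < 1.0 and mask.any():
        endo, epi = geometry.radii_mm[spec.slice]
        frac = (r - endo) / (epi - endo)
        mask &= frac >= (1.0 - spec.radial_extent)   # outer-wall banding
    return mask


def inject_artifact(
    series: ImageSeries,
    spec: ArtifactSpec,
    labels: np.ndarray,
    geometry: PhantomGeometry,
    seed: int | None = None,
) -> tuple[ImageSeries, np.ndarray]:
    """Multiply the artifact sector by a per-frame dropout factor.

    Returns the modified series and the boolean artifact truth mask.  A
    degenerate dropout range (1, 1) leaves the series unchanged and the
    mask empty.
    """
    lo, hi = spec.dropout
    if lo == hi == 1.0:
        return series.copy_with(), np.zeros(series.frames.shape[1:], dtype=bool)
    mask = artifact_mask(spec, labels, geometry)
    if not mask.any():
        raise ValueError("artifact sector does not intersect the annulus")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(lo, hi, size=len(series.frames))
    frames = series.frames.copy()
    for i, f in enumerate(factors):
        frames[i][mask] *= f
    return series.copy_with(frames=frames), mask


def random_shifts(n_frames: int, sd_px: float, rng) -> np.ndarray:
    """Random per-frame (row, col) shifts; frame 0 is kept still."""
    shifts = rng.normal(0.0, sd_px, size=(n_frames, 2))
    shifts[0] = 0.0
    return shifts


def apply_motion(series: ImageSeries, shifts: np.ndarray) -> tuple[ImageSeries, np.ndarray]:
    """Translate each frame by its (row, col) shift with linear interpolation.

    Returns the shifted series and the shift log for registration
    validation.  Shifts beyond a quarter of the grid are rejected.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (len(series.frames), 2):
        raise ValueError("one (row, col) shift per frame required")
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shifts must be finite")
    limit = series.frames.shape[1] / 4.0
    if np.any(np.abs(shifts) > limit):
        raise ValueError(f"shift magnitude exceeds a quarter grid ({limit:.1f} px)")
    frames = np.stack(
        [
            ndimage.shift(frame, s, order=1, mode="constant", cval=0.0)
            for frame, s in zip(series.frames, shifts)
        ]
    )
    frames = np.clip(frames, 0.0, None)
    return series.copy_with(frames=frames), shifts


# ---------------------------------------------------------------------------
# observer remeasurement


def simulate_observer_remeasurement(
    table: pd.DataFrame,
    observer_noise_sd: float,
    bias: float = 0.0,
    seed: int | None = None,
    observers: tuple[str, str] = ("O1", "O1"),
) -> pd.DataFrame:
    """Duplicate segment measurements with independent Gaussian perturbation.

    Each input row yields two replicates; replicate 2 additionally carries
    ``bias`` (ms).  Equal observer labels emulate intra-observer repeats;
    distinct labels an independent second reader.
    """
    if observer_noise_sd < 0:
        raise ValueError("observer noise SD must be >= 0")
    if table.empty:
        raise ValueError("segment table is empty")
    rng = np.random.default_rng(seed)
    reps = []
    for rep, (obs, extra) in enumerate(zip(observers, (0.0, bias)), start=1):
        df = table.copy()
        df["value"] = (
            df["value"].to_numpy()
            + extra
            + rng.normal(0.0, observer_noise_sd, len(df))
        )
        df["replicate"] = rep
        df["observer"] = obs
        reps.append(df)
    return pd.concat(reps, ignore_index=True)
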