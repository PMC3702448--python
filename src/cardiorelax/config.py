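"""Configuration objects and the packaged reference configuration.

All configuration is plain dataclasses so that a pipeline run is fully
determined by (config, seed).  The packaged reference configuration encodes
the simulated healthy-volunteer cohort: per-slice geometric-mean relaxation
times, multiplicative inter-subject scatter factors, covariate distributions
and the acquisition timing scheme.

Coordinate convention used throughout the package: pixel-centre coordinates,
0-based indices, angles measured counter-clockwise from the +x axis with +y
pointing up (i.e. toward decreasing row index).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

SLICES = ("base", "middle", "apex")
MAP_KINDS = ("t2", "t1_pre", "t1_post")

#: series kind <-> map kind correspondence
SERIES_FOR_MAP = {"t2": "t2prep", "t1_pre": "molli_pre", "t1_post": "molli_post"}
MAP_FOR_SERIES = {v: k for k, v in SERIES_FOR_MAP.items()}

T2PREP_TIMES_MS = (0.0, 24.0, 55.0)
MOLLI_BASE_TI_MS = (100.0, 180.0, 260.0)
MOLLI_GROUP_SIZES = (3, 3, 5)

#: fixed non-myocardial tissue values (ms); blood T1 exceeds myocardium
#: pre-contrast and falls below it post-contrast
BLOOD_VALUES = {"t2": 250.0, "t1_pre": 1900.0, "t1_post": 300.0}

#: uniform proton-density scale of tissue in arbitrary units
TISSUE_S0 = 100.0


class ConfigurationError(ValueError):
    """Invalid cohort / geometry / pipeline configuration."""


@dataclass(frozen=True)
class HeartRateDistribution:
    mean: float = 70.0
    sd: float = 6.0
    min: float = 47.0
    max: float = 102.0
    split: float = 69.5


@dataclass(frozen=True)
class BloodPressureDistribution:
    systolic_mean: float = 132.0
    systolic_sd: float = 12.0
    diastolic_mean: float = 72.0
    diastolic_sd: float = 11.0


@dataclass(frozen=True)
class CohortConfig:
    """Statistical structure of the simulated cohort.

    ``reference_values[map_kind][slice]`` are geometric means in ms;
    ``scatter_factors[map_kind]`` are multiplicative inter-subject SDs
    (>= 1).  ``hr_effect[map_kind][slice]``, when present, multiplies the
    subject's truth for that map type when the subject's heart rate exceeds
    ``heart_rate.split``; ``age_effect_t1_pre`` multiplies pre-contrast T1
    in the oldest age band.  Setting either to ``None`` disables the effect.
    """

    n_per_stratum: int = 10
    n_total: int | None = None
    age_bands: tuple[tuple[float, float], ...] = ((20, 39), (40, 59), (60, 80))
    reference_values: dict = field(default_factory=dict)
    scatter_factors: dict = field(default_factory=dict)
    hr_effect: dict | None = None
    age_effect_t1_pre: float | None = None
    heart_rate: HeartRateDistribution = field(default_factory=HeartRateDistribution)
    blood_pressure: BloodPressureDistribution = field(
        default_factory=BloodPressureDistribution
    )

    def validate(self) -> None:
        if self.n_total is None and self.n_per_stratum < 1:
            raise ConfigurationError("n_per_stratum must be >= 1")
        if self.n_total is not None and self.n_total < 2:
            raise ConfigurationError("n_total must be >= 2")
        if len(self.age_bands) != 3:
            raise ConfigurationError("exactly three age bands expected")
        bands = sorted(self.age_bands)
        for (lo, hi), (lo2, _hi2) in zip(bands, bands[1:]):
            if hi >= lo2:
                raise ConfigurationError("age bands must be disjoint")
        for kind, per_slice in self.reference_values.items():
            for sl, v in per_slice.items():
                if not v > 0:
                    raise ConfigurationError(
                        f"reference value {kind}/{sl} must be positive, got {v}"
                    )
        for kind, sf in self.scatter_factors.items():
            if not sf >= 1.0:
                raise ConfigurationError(
                    f"scatter factor {kind} must be >= 1, got {sf}"
                )
        if not self.heart_rate.min < self.heart_rate.max:
            raise ConfigurationError("heart-rate range empty")


@dataclass(frozen=True)
class PhantomGeometry:
    """Three-slice short-axis annulus geometry.

    Radii in mm; isotropic pixel spacing; ``rv_insertion_angle`` is the
    anterior RV insertion, degrees counter-clockwise from +x (y up).
    """

    grid_size: int = 96
    pixel_spacing_mm: float = 1.5
    radii_mm: dict = field(
        default_factory=lambda: {
            "base": (22.0, 32.0),
            "middle": (19.0, 29.0),
            "apex": (14.0, 23.0),
        }
    )
    rv_insertion_angle: float = 120.0

    def validate(self) -> None:
        if self.grid_size < 16:
            raise ConfigurationError("grid too small")
        if not self.pixel_spacing_mm > 0:
            raise ConfigurationError("pixel spacing must be positive")
        for sl in SLICES:
            endo, epi = self.radii_mm[sl]
            if not 0 < endo < epi:
                raise ConfigurationError(f"degenerate radii for slice {sl!r}")
        for sl in ("middle", "apex"):
            if not (
                self.radii_mm[sl][0] < self.radii_mm["base"][0]
                and self.radii_mm[sl][1] < self.radii_mm["base"][1]
            ):
                raise ConfigurationError("apical/mid radii must shrink toward apex")


@dataclass(frozen=True)
class ArtifactSpec:
    """Susceptibility-artifact model: a wall sector whose signal is
    modulated per frame by a dropout factor in [0, 1]."""

    slice: str = "middle"
    center_angle: float = 330.0     # inferolateral sector centre for rv=120
    angular_extent: float = 60.0
    radial_extent: float = 1.0      # fraction of wall thickness affected
    dropout: tuple[float, float] = (0.3, 0.9)  # per-frame factor range
    probability: float = 0.08       # per subject-slice

    def validate(self) -> None:
        lo, hi = self.dropout
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("dropout factors must lie in [0, 1]")
        if not 0.0 <= self.angular_extent < 360.0:
            raise ConfigurationError("angular extent must lie in [0, 360)")
        if not 0.0 < self.radial_extent <= 1.0:
            raise ConfigurationError("radial extent must lie in (0, 1]")


@dataclass(frozen=True)
class FitOptions:
    """Bounds, tolerances and skip rules for the pixel-wise fits.

    Clamp ranges flag rather than truncate: an optimum outside the
    physiologic range marks the pixel non-converged.
    """

    t2_clamp_ms: tuple[float, float] = (1.0, 300.0)
    t1_clamp_ms: tuple[float, float] = (1.0, 5000.0)
    t2_search_ms: tuple[float, float] = (0.5, 1000.0)
    t1_star_search_ms: tuple[float, float] = (20.0, 6000.0)
    tolerance: float = 1e-10
    max_iter: int = 200
    min_signal_factor: float = 5.0   # x noise-floor estimate; peak below -> skip

    def validate(self) -> None:
        for lo, hi in (self.t2_clamp_ms, self.t1_clamp_ms,
                       self.t2_search_ms, self.t1_star_search_ms):
            if not 0 < lo < hi:
                raise ConfigurationError("bounds must be ordered and positive")
        if not self.tolerance > 0:
            raise ConfigurationError("tolerance must be positive")


@dataclass(frozen=True)
class QCThresholds:
    """Rule-based proxies for visual quality reading."""

    rmse_multiplier: float = 3.0        # x slice-median RMSE flags a pixel
    max_artifact_fraction: float = 0.10  # segment excluded above this
    propagate_registration: bool = True
    mistrigger_tolerance_ms: float = 10.0

    def validate(self) -> None:
        if not self.rmse_multiplier > 0:
            raise ConfigurationError("rmse multiplier must be positive")
        if not 0 < self.max_artifact_fraction <= 1:
            raise ConfigurationError("artifact fraction threshold must be in (0, 1]")
        if not self.mistrigger_tolerance_ms > 0:
            raise ConfigurationError("mistrigger tolerance must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything an end-to-end reference experiment needs besides the seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    fit_options: FitOptions = field(default_factory=FitOptions)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    noise_sd: float = 1.0
    ba_ratio: float = 2.2
    erosion_fraction: float = 0.15
    motion_sd_px: float = 0.5
    artifact: ArtifactSpec | None = field(default_factory=ArtifactSpec)
    register: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.geometry.validate()
        self.fit_options.validate()
        self.qc_thresholds.validate()
        if self.artifact is not None:
            self.artifact.validate()
        if not self.noise_sd >= 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.ba_ratio > 1:
            raise ConfigurationError("ba_ratio must exceed 1")
        if not 0 <= self.erosion_fraction < 0.5:
            raise ConfigurationError("erosion fraction must be in [0, 0.5)")


def _load_packaged_yaml() -> dict:
    ref = importlib.resources.files("cardiorelax").joinpath(
        "data/reference_config.yaml"
    )
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_reference_config(
    n_total: int | None = None,
    hr_effect: bool = False,
    age_effect: bool = False,
) -> CohortConfig:
    """Build the packaged reference :class:`CohortConfig`.

    With ``hr_effect=True`` the map types with a heart-rate dependence use
    the below-median group means as slice references and the above/below
    ratio as the multiplicative shift for above-median subjects, so the
    configured group means are exactly the packaged split values.
    """
    raw = _load_packaged_yaml()
    refs = {k: dict(v) for k, v in raw["reference_values"].items()}
    hr = None
    if hr_effect:
        hr = {}
        for kind, per_slice in raw["hr_split_means"].items():
            hr[kind] = {}
            for sl, (below, above) in per_slice.items():
                refs[kind][sl] = float(below)
                hr[kind][sl] = float(above) / float(below)
    c = raw["cohort"]
    cfg = CohortConfig(
        n_per_stratum=int(c["n_per_stratum"]),
        n_total=n_total,
        age_bands=tuple(tuple(b) for b in c["age_bands"]),
        reference_values=refs,
        scatter_factors={k: float(v) for k, v in raw["scatter_factors"].items()},
        hr_effect=hr,
        age_effect_t1_pre=float(raw["age_effect_t1_pre"]) if age_effect else None,
        heart_rate=HeartRateDistribution(**{k: float(v) for k, v in c["heart_rate"].items()}),
        blood_pressure=BloodPressureDistribution(
            **{k: float(v) for k, v in c["blood_pressure"].items()}
        ),
    )
    cfg.validate()
    return cfg


def load_observer_settings() -> dict:
    """Packaged observer-agreement settings (bias / SD of paired differences, ms)."""
    return _load_packaged_yaml()["observer"]


def reference_pipeline_config(
    n_total: int = 40, hr_effect: bool = False, seed: int = 0, **overrides
) -> PipelineConfig:
    """The packaged end-to-end reference experiment configuration."""
    cohort = load_reference_config(n_total=n_total, hr_effect=hr_effect)
    cfg = PipelineConfig(cohort=cohort, seed=seed, **overrides)
    cfg.validate()
    return cfg


def pipeline_config_from_yaml(path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a user YAML file.

    Recognised top-level keys mirror the dataclass fields; missing keys fall
    back to packaged defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {})
    hr_effect = bool(cohort_raw.pop("hr_effect", False))
    n_total = cohort_raw.pop("n_total", None)
    cohort = load_reference_config(n_total=n_total, hr_effect=hr_effect)
    if cohort_raw:
        cohort = replace(cohort, **cohort_raw)
    geometry = PhantomGeometry(**raw.pop("geometry", {}))
    fit_options = FitOptions(**raw.pop("fit_options", {}))
    qc = QCThresholds(**raw.pop("qc_thresholds", {}))
    art_raw = raw.pop("artifact", "default")
    if art_raw is None:
        artifact = None
    elif art_raw == "default":
        artifact = ArtifactSpec()
    else:
        artifact = ArtifactSpec(**art_raw)
    cfg = PipelineConfig(
        cohort=cohort,
        geometry=geometry,
        fit_options=fit_options,
        qc_thresholds=qc,
        artifact=artifact,
        **raw,
    )
    cfg.validate()
    return cfg
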