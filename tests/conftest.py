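"""Shared fixtures: small phantom geometries, cohorts and synthetic tables."""

import numpy as np
import pandas as pd
import pytest

from cardiorelax.config import PhantomGeometry, load_reference_config
from cardiorelax.phantom import SEGMENT_IDS, build_cohort, render_ground_truth


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    return PhantomGeometry(
        grid_size=64,
        pixel_spacing_mm=2.2,
        radii_mm={"base": (22.0, 32.0), "middle": (19.0, 29.0), "apex": (14.0, 23.0)},
    )


@pytest.fixture(scope="session")
def reference_config():
    return load_reference_config()


@pytest.fixture(scope="session")
def cohort(reference_config):
    return build_cohort(reference_config, seed=0)


@pytest.fixture(scope="session")
def subject(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def truth_middle(subject, geometry):
    return render_ground_truth(subject, geometry, "middle")


@pytest.fixture(scope="session")
def truth_base(subject, geometry):
    return render_ground_truth(subject, geometry, "base")


def synthetic_segment_table(subjects, map_kind, noise_sd=0.5, seed=0):
    """Segment table straight from ground truth plus measurement noise.

    Bypasses the imaging chain; used to test the statistics layer against
    known generator parameters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        for sl, segs in SEGMENT_IDS.items():
            for seg in segs:
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "map_kind": map_kind,
                        "slice": sl,
                        "segment": seg,
                        "value": s.segment_truth(map_kind, seg)
                        + rng.normal(0, noise_sd),
                        "eligible": True,
                        "n_pixels": 100,
                        "age_band": s.age_band,
                        "sex": s.sex,
                        "heart_rate": s.heart_rate,
                        "systolic_bp": s.systolic_bp,
                        "diastolic_bp": s.diastolic_bp,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def segment_table_t2(cohort):
    return synthetic_segment_table(cohort, "t2", noise_sd=0.5, seed=1)
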