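"""Shared fixtures: small canvases and seeded synthetic cohorts.

Cohort-level fixtures run on a reduced canvas (64 x 114, the same aspect
ratio as the 513 x 911 standard face) so that repeated generation stays
fast; the ROI geometry scales with the canvas by construction.
"""

import numpy as np
import pytest

from sto2stress.roi_features import default_geometry
from sto2stress.synthetic import CohortConfig, generate_cohort

SMALL_SHAPE = (64, 114)


@pytest.fixture(scope="session")
def small_shape():
    return SMALL_SHAPE


@pytest.fixture(scope="session")
def small_geometry():
    return default_geometry(SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort (n=42, 5 conditions) on the small canvas."""
    config = CohortConfig(canvas_shape=SMALL_SHAPE, seed=20)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort, small_geometry):
    from sto2stress.roi_features import build_feature_table

    cohort, _ = small_cohort
    return build_feature_table(cohort, small_geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
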