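import numpy as np
import pytest

from lungkit.cohort import StudyScale, simulate_study
from lungkit.phantom import PhantomSpec, make_gated_projection_set


@pytest.fixture(scope="session")
def small_spec():
    """Healthy 48^3 phantom used by most pipeline tests."""
    return PhantomSpec.with_grid(48, severity=0.0, seed=7)


@pytest.fixture(scope="session")
def gated_set(small_spec):
    """One gated projection acquisition of the small phantom (240 views)."""
    return make_gated_projection_set(small_spec, n_angles=240,
                                     rotation_time=270.0)


@pytest.fixture(scope="session")
def cohort_table():
    """The standard synthetic study: 3 arms x 5 animals x 4 days, seed 1."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def study_scale():
    return StudyScale()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
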