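import numpy as np
import pytest

from thasim import CohortConfig, DEFAULT_IMPLANT, cohort_sweep, generate_cohort


@pytest.fixture(scope="session")
def spec():
    """The study implant: 32 mm head, 9 mm neck, 130 degree neck-shaft angle."""
    return DEFAULT_IMPLANT


@pytest.fixture(scope="session")
def study_cohort():
    """Seeded 32-hip synthetic cohort at the published distribution defaults."""
    return generate_cohort(CohortConfig(n=32, seed=0))


@pytest.fixture(scope="session")
def study_sweeps(spec, study_cohort):
    """Default rotation x adduction sweeps of the 32-hip cohort, both postures."""
    return cohort_sweep(spec, study_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_vectors(rng, n, max_polar_deg):
    """Uniform-azimuth unit vectors with polar angle below max_polar_deg."""
    theta = np.deg2rad(rng.uniform(0.0, max_polar_deg, n))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
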