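import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_config():
    """A study small enough for fast end-to-end tests."""
    from strucdyn.synthetic import SyntheticStudyConfig

    return SyntheticStudyConfig(
        n_regions=12,
        n_subjects=6,
        n_timepoints=240,
        tau_noise_sd=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from strucdyn.synthetic import generate_study

    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The full default (HCP-like) synthetic study, shared across tests."""
    from strucdyn.synthetic import SyntheticStudyConfig, generate_study

    return generate_study(SyntheticStudyConfig(seed=1))


@pytest.fixture(scope="session")
def medium_study():
    """Default dimensions but fewer subjects, for feature-heavy analyses."""
    from strucdyn.synthetic import SyntheticStudyConfig, generate_study

    return generate_study(SyntheticStudyConfig(n_subjects=20, seed=3))


def ar1_series(rng, phi, n, burn=500):
    from scipy.signal import lfilter

    e = rng.standard_normal(n + burn)
    return lfilter([1.0], [1.0, -phi], e)[burn:]
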