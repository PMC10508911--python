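import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from magphage.simulate import SimulationConfig, simulate_cohort  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_config():
    """Small cohort with exact region calls (no jitter, misses or false calls)."""
    return SimulationConfig(
        seed=11, n_individuals=3, n_mags_per_individual=3,
        boundary_jitter_sd=0.0, region_fnr=0.0, region_fpr=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return simulate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort with the default noise settings."""
    return simulate_cohort(SimulationConfig(seed=7, n_individuals=3, n_mags_per_individual=3))
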