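import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared by read-only tests."""
    from berryroad.synthetic import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_cultivars=12, n_fruit_per_cultivar=3, seed=42)
    truth, curves, peaks, genotypes = simulate_cohort(cfg)
    return cfg, truth, curves, peaks, genotypes
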