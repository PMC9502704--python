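import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Five 30-minute hya-profile recordings, one per subject."""
    from wristgait.simulate import SimConfig, simulate_cohort

    cfg = SimConfig.for_profile("hya", duration_s=1800.0, seed=2)
    return simulate_cohort(5, cfg, days=1)


@pytest.fixture(scope="session")
def one_recording(small_cohort):
    return small_cohort[0]
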