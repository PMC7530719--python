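import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_component_sample(rng):
    """Log-normal mixture with the canonical low/high setpoint geometry."""
    lo = rng.normal(0.8, 0.25, 2400)
    hi = rng.normal(1.6, 0.25, 1600)
    return np.exp(np.concatenate([lo, hi]))
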