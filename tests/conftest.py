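import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neutralherb import EventParams, SynthConfig, generate_survey

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def event_default():
    return EventParams()


@pytest.fixture
def small_bounds():
    """Bounds far from saturation, for CLT-regime checks."""
    return EventParams(5e-5, 1e-2)


@pytest.fixture
def neutral_survey():
    return generate_survey(SynthConfig(seed=42), EventParams())
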