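import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phytosds import make_proportional_bins, make_uniform_bins

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def prop_bins():
    """Default proportional grid: 24 geometric bins over 0.5-100 µm."""
    return make_proportional_bins(0.5, 100.0, 24)


@pytest.fixture
def uniform_bins():
    """100 uniform 1 µm bins over 0.5-100.5 µm."""
    return make_uniform_bins(0.5, 100.5, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
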