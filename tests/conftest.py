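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
def well_separated_pair():
    """Equal-weight N(0,1) + N(10,1): trivially resolvable two-component mix."""
    return [(0.5, 0.0, 1.0), (0.5, 10.0, 1.0)]
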