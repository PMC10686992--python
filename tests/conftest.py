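import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def path_network():
    """4-node path u0-v0-w1-x1 with groups given by the suffix."""
    edges = [("u0", "v0"), ("v0", "w1"), ("w1", "x1")]
    labels = {"u0": "0", "v0": "0", "w1": "1", "x1": "1"}
    return edges, labels
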