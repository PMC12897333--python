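import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net():
    """A small-width detector shared by forward-pass tests."""
    from splashquant.model import ModelConfig, build_model

    cfg = ModelConfig(input_size=(64, 64), width_multiple=0.25, seed=7)
    return build_model(cfg).eval()
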