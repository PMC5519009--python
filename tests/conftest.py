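import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def best_noise():
    """Noise scales of the best-fitting (NE-cd) observer."""
    from mot3d import NoiseParams

    return NoiseParams(c=0.0082, d=0.0202)


@pytest.fixture(scope="session")
def design():
    from mot3d import build_experiment_design

    return build_experiment_design()
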