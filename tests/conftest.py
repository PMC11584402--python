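import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smpc.synthetic import SimulationConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def small_config():
    """Scaled-down FOV (same 100 um side, coarser sampling) for speed."""
    return SimulationConfig(seed=0, fov_px=200, um_per_px=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
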