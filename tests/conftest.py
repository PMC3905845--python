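import numpy as np
import pytest

from halodyn.simdata import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small fast field for geometry/timelapse tests."""
    return SimConfig(image_shape=(128, 128), n_frames=8, rng_seed=1)


@pytest.fixture
def frap_config():
    """150-frame acquisition grid used by the trace simulators."""
    return SimConfig(n_frames=150, rng_seed=1)
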