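import numpy as np
import pytest

from wavemap import make_phantom_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def piecewise_phantom():
    return make_phantom_image(64, "piecewise", seed=7)


@pytest.fixture(scope="session")
def smooth_phantom():
    return make_phantom_image(128, "smooth_textured", seed=7)
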