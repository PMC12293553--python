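import numpy as np
import pytest

from sfmtools import RgbImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A small random RGB image factory."""

    def make(h=12, w=12, low=0.0, high=255.0):
        return RgbImage(rng.uniform(low, high, size=(h, w, 3)))

    return make
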