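import numpy as np
import pytest

from ttmlab.imagecore import LuminanceImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng):
    """A 64x64 random luminance image with standard geometry."""
    return LuminanceImage(rng.random((64, 64)), ppd=16.0, fixation=(31.5, 31.5))


@pytest.fixture
def tiny_image(rng):
    """16x16 image for oracle-level comparisons."""
    return LuminanceImage(rng.random((16, 16)), ppd=8.0, fixation=(7.5, 7.5))
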