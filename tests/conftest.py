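import numpy as np
import pytest

from vesselset import IntensityImage, two_block_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng):
    """Random 8×8 intensity field on the 0–255 scale."""
    return IntensityImage(values=rng.uniform(0, 255, size=(8, 8)))


@pytest.fixture
def noisy_two_block():
    """64×64 two-class fixture (50 / 200, σ = 5) with a fixed seed."""
    return two_block_fixture((64, 64), 50.0, 200.0, 5.0, seed=1)
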