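import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_image():
    """Piecewise-constant two-region test image: dark disk on bright field."""
    h = w = 64
    rr, cc = np.mgrid[0:h, 0:w]
    disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 15**2
    img = np.where(disk, 0.2, 0.8)
    return img, disk
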