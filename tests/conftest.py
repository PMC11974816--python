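import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_mask():
    """Boolean disc of radius 30 in a 101x101 frame, with coordinates."""
    rr, cc = np.mgrid[0:101, 0:101]
    return (rr - 50) ** 2 + (cc - 50) ** 2 <= 30 ** 2
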