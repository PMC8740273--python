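import numpy as np
import pytest

from drpipe import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fundus_params():
    return synth.FundusParams(side=48, border=4)


@pytest.fixture
def fundus_image(fundus_params):
    return synth.make_fundus(fundus_params)


def random_grid(rng, max_side=20):
    """Random small pixel grid, possibly with dark borders."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    img = rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8)
    # dark out a random border frame to exercise trimming
    top, bottom = rng.integers(0, h // 2 + 1, size=2)
    left, right = rng.integers(0, w // 2 + 1, size=2)
    if top:
        img[:top] = rng.integers(0, 7, size=(top, w, 3))
    if bottom:
        img[h - bottom :] = rng.integers(0, 7, size=(bottom, w, 3))
    if left:
        img[:, :left] = rng.integers(0, 7, size=(h, left, 3))
    if right:
        img[:, w - right :] = rng.integers(0, 7, size=(h, right, 3))
    return img
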