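import numpy as np
import pytest


def make_disk(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


def make_ring(shape, center, r_in, r_out):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(yy - center[0], xx - center[1])
    return (r >= r_in) & (r < r_out)


def fused_disks(shape, centers, radius):
    mask = np.zeros(shape, dtype=bool)
    for c in centers:
        mask |= make_disk(shape, c, radius)
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(42)
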