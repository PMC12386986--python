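import numpy as np
import pytest

from fractalrad.core import DiscretizedROI, GrayImage, ROIMask


@pytest.fixture
def full_mask():
    def _make(shape):
        return ROIMask(np.ones(shape, dtype=bool))

    return _make


@pytest.fixture
def ramp_image():
    """I(x, y) = x: increments are exactly linear in distance (H = 1)."""

    def _make(side=16):
        return GrayImage(np.tile(np.arange(float(side)), (side, 1)))

    return _make


def make_roi(levels, mask=None, n_levels=None):
    """Build a DiscretizedROI straight from a small integer array."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    mask = np.asarray(mask, dtype=bool)
    if n_levels is None:
        n_levels = max(2, int(levels[mask].max()))
    lv = np.where(mask, levels, 0)
    return DiscretizedROI(lv, mask, n_levels)


@pytest.fixture
def roi_factory():
    return make_roi


@pytest.fixture
def random_roi_factory():
    """Random small ROIs with random masks, for oracle-equivalence sweeps."""

    def _make(seed, shape=(6, 6), n_levels=4):
        rng = np.random.default_rng(seed)
        levels = rng.integers(1, n_levels + 1, size=shape)
        mask = rng.random(shape) < 0.8
        if mask.sum() < 4:
            mask[:2, :2] = True
        return make_roi(np.where(mask, levels, 0), mask, n_levels)

    return _make
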