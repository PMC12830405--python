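import numpy as np
import pytest

from geldose.volumes import ScalarVolume, VOIMask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    return VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0), (-7.0, -7.0, -7.0))


def make_volume(grid, values, unit="Gy"):
    return ScalarVolume(grid, np.asarray(values, dtype=float), unit)


def full_mask(grid, label="all"):
    return VOIMask(grid, np.ones(grid.shape, bool), label)
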