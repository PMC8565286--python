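import numpy as np
import pytest

from qda.io_volumes import BoldVolume, BrainMask, TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_mask():
    """6x5x4 mask with an irregular boundary."""
    grid = np.zeros((6, 5, 4), dtype=bool)
    grid[1:5, 1:4, 1:3] = True
    grid[2, 2, 0] = True
    return BrainMask(grid=grid, voxel_size_mm=np.array([4.0, 4.0, 4.0]))


@pytest.fixture
def toy_volume(rng, small_mask):
    data = rng.standard_normal((*small_mask.shape, 40))
    return BoldVolume(
        data=data, voxel_size_mm=small_mask.voxel_size_mm, tr_s=2.5
    )


def make_ts(values, tr_s=2.5):
    """TimeSeriesMatrix with dummy voxel coordinates."""
    values = np.asarray(values, dtype=float)
    coords = np.column_stack(
        [np.arange(len(values)), np.zeros(len(values)), np.zeros(len(values))]
    )
    return TimeSeriesMatrix(values=values, voxel_index=coords, tr_s=tr_s)


@pytest.fixture
def ts_factory():
    return make_ts
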