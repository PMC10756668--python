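import numpy as np
import pytest

from adaptdose.core import BinaryMask, DoseGrid, ImageGrid3D


@pytest.fixture
def unit_grid():
    """1 mm isotropic grid, 40^3, origin at voxel-centre (0.5, 0.5, 0.5)."""
    return ImageGrid3D(origin=(0.5, 0.5, 0.5), spacing=(1, 1, 1), shape=(40, 40, 40))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_dose(grid: ImageGrid3D, rng: np.random.Generator, top: float = 60.0) -> DoseGrid:
    return DoseGrid(grid, rng.uniform(0.0, top, size=grid.shape))


def random_mask(grid: ImageGrid3D, rng: np.random.Generator, p: float = 0.3) -> BinaryMask:
    return BinaryMask(grid, rng.random(grid.shape) < p)


@pytest.fixture
def coarse_cohort_grid():
    from adaptdose.synthetic_cohort import make_grid

    return make_grid((2.5, 2.5, 2.5))
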