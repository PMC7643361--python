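import numpy as np
import pytest

from vimtarget.grids import BinaryMask, VoxelGrid
from vimtarget.pipeline import analyze_cohort
from vimtarget.synthetic import generate_cohort


@pytest.fixture
def grid10() -> VoxelGrid:
    return VoxelGrid((10, 10, 10))


def random_mask(grid: VoxelGrid, seed: int, p: float = 0.2) -> BinaryMask:
    rng = np.random.default_rng(seed)
    return BinaryMask(grid, rng.random(grid.dims) < p)


@pytest.fixture(scope="session")
def seed0_cohort():
    """The default 14-patient synthetic cohort, seed 0, full 96 mm grid."""
    return generate_cohort(rng_seed=0)


@pytest.fixture(scope="session")
def seed0_analysis(seed0_cohort):
    """Full pipeline analysis of the seed-0 default cohort."""
    return analyze_cohort(seed0_cohort)
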