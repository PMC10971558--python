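import numpy as np
import pytest

from fusht.grids import SimulationGrid
from fusht.materials import MaterialMap, Medium, WATER


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_grid():
    """Cube of 1 mm voxels, small enough for brute-force checks."""
    return SimulationGrid((1e-3, 1e-3, 1e-3), (7, 7, 9))


@pytest.fixture
def uniform_tissue(tiny_grid):
    medium = Medium("tissue", 1060.0, 1560.0, 9.32, 0.5, 3700.0, 0.0)
    return MaterialMap.uniform(tiny_grid, medium)


def single_voxel_map(conductivity=0.5, perfusion=0.0, density=1060.0,
                     specific_heat=3700.0):
    grid = SimulationGrid((1e-3, 1e-3, 1e-3), (1, 1, 1))
    medium = Medium("toy", density, 1500.0, 0.0, conductivity, specific_heat,
                    perfusion)
    return MaterialMap.uniform(grid, medium)
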