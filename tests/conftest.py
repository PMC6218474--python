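import numpy as np
import pytest

from hfprisk.grid import Grid
from hfprisk.hfp_builder import HFPMap, PressureStack
from hfprisk.synthetic_data import SimConfig, simulate


def empty_layers(grid: Grid) -> dict[str, np.ndarray]:
    """All-zero pressure: no land use, nobody, unlit, infinitely far lines."""
    return {
        "built": np.zeros(grid.shape, dtype=bool),
        "crop": np.zeros(grid.shape, dtype=bool),
        "pasture": np.zeros(grid.shape, dtype=bool),
        "popdensity": np.zeros(grid.shape),
        "nightlights": np.zeros(grid.shape),
        "railways": np.full(grid.shape, np.inf),
        "roads": np.full(grid.shape, np.inf),
        "waterways": np.full(grid.shape, np.inf),
    }


def make_stack(grid: Grid, epoch: int = 1993, **overrides) -> PressureStack:
    layers = empty_layers(grid)
    layers.update(overrides)
    return PressureStack(grid=grid, epoch=epoch, layers=layers)


def hfp_from_values(values, epoch: int = 1993) -> HFPMap:
    values = np.asarray(values, dtype=np.int64)
    grid = Grid(rows=values.shape[0], cols=values.shape[1])
    return HFPMap(grid=grid, epoch=epoch, values=values)


@pytest.fixture
def grid5() -> Grid:
    return Grid(rows=5, cols=5)


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic world shared across tests that only read it."""
    return simulate(SimConfig(rows=60, cols=60, n_species=40, seed=7))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(rows=60, cols=60, n_species=40, seed=7)
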