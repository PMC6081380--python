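import numpy as np
import pytest

from landmit import grid as gridmod
from landmit.pipeline import StudyContext


@pytest.fixture(scope="session")
def small_grid():
    """Coarse test grid (24 x 18) with the same synthetic land mask."""
    return gridmod.make_grid(n_lat=18, n_lon=24)


@pytest.fixture(scope="session")
def small_biomes(small_grid):
    return gridmod.biome_map(small_grid)


@pytest.fixture(scope="session")
def ctx_small():
    """Shared study context on the coarse grid with two ensemble members."""
    return StudyContext.build(n_lat=18, n_lon=24, n_members=2, seed=7)


@pytest.fixture(scope="session")
def ctx_desk():
    """Desk-scale context (48 x 36) used by the heavier end-to-end checks."""
    return StudyContext.build(n_lat=36, n_lon=48, n_members=8, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
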