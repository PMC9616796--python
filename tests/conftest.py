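import numpy as np
import pytest

from escapenav.arena import CompiledWorld, GridWorld, build_gridworld


@pytest.fixture(scope="session")
def arena4() -> GridWorld:
    return build_gridworld(4)


@pytest.fixture(scope="session")
def compiled4(arena4) -> CompiledWorld:
    return CompiledWorld(arena4)


@pytest.fixture()
def open_world() -> GridWorld:
    """A fully open 9x9 lattice with start and goal in opposite corners."""
    occ = np.ones((9, 9), dtype=bool)
    return GridWorld(occ, start_cell=(8, 8), goal_cell=(0, 0))


@pytest.fixture()
def corridor() -> GridWorld:
    """A 1x8 corridor; goal at the right end."""
    occ = np.zeros((3, 8), dtype=bool)
    occ[1, :] = True
    return GridWorld(occ, start_cell=(1, 0), goal_cell=(1, 7))
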