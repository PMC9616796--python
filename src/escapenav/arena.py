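"""Arena geometry, grid-world environments, reward dynamics and path oracles.

Coordinate convention
---------------------
Cells are addressed as ``(row, col)``, 0-based, with row 0 at the top of the
lattice. Continuous positions use the same axes, so a cell's center is simply
``(float(row), float(col))``. The shelter (goal) platform sits at the top of
the packaged arenas and the threat (start) platform at the bottom.

The environment is an elevated two-path maze: a threat platform and a shelter
platform connected by a left and a right arm of different geodesic length.
Arenas are described at two levels: an :class:`ArenaSpec` holds the physical
geometry (path lengths in cm, initial path angles), while a :class:`GridWorld`
is the discrete 50x50 occupancy lattice the reinforcement-learning agents
navigate, packaged as text-mask fixtures.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .config import REWARD_DEFAULTS
from .errors import ConfigurationError, ContractViolationError, ValidationError

Cell = tuple[int, int]

#: Sentinel returned by :func:`shortest_path_length` when no path exists.
UNREACHABLE = math.inf


# ---------------------------------------------------------------------------
# Actions
# ---------------------------------------------------------------------------

class Action(Enum):
    """The 8 cardinal movement directions, in canonical tie-break order."""

    UP = (-1, 0)
    UP_RIGHT = (-1, 1)
    RIGHT = (0, 1)
    DOWN_RIGHT = (1, 1)
    DOWN = (1, 0)
    DOWN_LEFT = (1, -1)
    LEFT = (0, -1)
    UP_LEFT = (-1, -1)

    @property
    def displacement(self) -> Cell:
        return self.value


ACTIONS: tuple[Action, ...] = tuple(Action)
#: displacement array in canonical order, shape (8, 2)
ACTION_DISPLACEMENTS = np.array([a.value for a in ACTIONS], dtype=np.int64)
_DISP_TO_ACTION = {a.value: a for a in ACTIONS}


def action_from_displacement(drow: int, dcol: int) -> Action:
    """Look up the action for a unit displacement; raises if not a king move."""
    try:
        return _DISP_TO_ACTION[(drow, dcol)]
    except KeyError:
        raise ContractViolationError(
            f"displacement ({drow}, {dcol}) is not a single 8-neighbor move")


# ---------------------------------------------------------------------------
# Arena geometry (physical specs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaSpec:
    """Physical geometry of one arena.

    Lengths are geodesic path lengths (cm) from threat to shelter platform
    along each arm; angles are the initial angle of each path relative to the
    direct shelter direction (degrees). The dimensionless ratios are defined
    as left / (left + right) for lengths and angles respectively.
    """

    arena_id: int | str
    left_length: float
    right_length: float
    left_angle: float
    right_angle: float

    def __post_init__(self):
        for name in ("left_length", "right_length", "left_angle", "right_angle"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    @property
    def geodesic_ratio(self) -> float:
        return self.left_length / (self.left_length + self.right_length)

    @property
    def angle_ratio(self) -> float:
        return self.left_angle / (self.left_angle + self.right_angle)

    @property
    def short_arm(self) -> str:
        """'left' or 'right' — the geodesically shorter escape path."""
        return "right" if self.right_length <= self.left_length else "left"

    def flipped(self) -> "ArenaSpec":
        """Mirror-image arena (left/right arms swapped), as in the dynamic
        arena after the bridge flip."""
        return replace(
            self,
            left_length=self.right_length, right_length=self.left_length,
            left_angle=self.right_angle, right_angle=self.left_angle,
        )


#: The five experimental arenas. Right arm is fixed at 505 cm for arenas
#: 1-4 while the left arm grows; arena 5 has equal lengths but an asymmetric
#: angle (right path initially points 90 degrees away from shelter).
ARENA_SPECS: dict[int | str, ArenaSpec] = {
    1: ArenaSpec(1, 505.0, 505.0, 45.0, 45.0),
    2: ArenaSpec(2, 770.0, 505.0, 45.0, 45.0),
    3: ArenaSpec(3, 872.0, 505.0, 45.0, 45.0),
    4: ArenaSpec(4, 1085.0, 505.0, 45.0, 45.0),
    5: ArenaSpec(5, 1085.0, 1085.0, 45.0, 90.0),
}
#: The dynamic arena starts in the arena-4 configuration; its flipped state
#: is ARENA_SPECS["dynamic"].flipped().
ARENA_SPECS["dynamic"] = replace(ARENA_SPECS[4], arena_id="dynamic")


# ---------------------------------------------------------------------------
# Grid world
# ---------------------------------------------------------------------------

REGION_CHARS = {"S": "shelter", "T": "threat", "L": "left_arm", "R": "right_arm"}


@dataclass
class GridWorld:
    """Discrete occupancy lattice with start (threat) and goal (shelter) cells.

    ``occupancy[r, c]`` is True where the agent may stand. ``regions`` maps
    region names ('shelter', 'threat', 'left_arm', 'right_arm', ...) to
    boolean masks of the same shape; packaged fixtures always carry the four
    canonical regions. Packaged arenas are 50x50; smaller lattices are
    accepted for tests and oracles.
    """

    occupancy: np.ndarray
    start_cell: Cell
    goal_cell: Cell
    arena_id: int | str | None = None
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise ValidationError("occupancy must be a 2-D lattice")
        self.start_cell = tuple(int(v) for v in self.start_cell)
        self.goal_cell = tuple(int(v) for v in self.goal_cell)
        for name, cell in (("start_cell", self.start_cell),
                           ("goal_cell", self.goal_cell)):
            if not self.is_accessible(cell):
                raise ValidationError(f"{name} {cell} is not accessible")

    # -- basic queries ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    @property
    def n_accessible(self) -> int:
        return int(self.occupancy.sum())

    def accessible_cells(self) -> list[Cell]:
        rows, cols = np.nonzero(self.occupancy)
        return [(int(r), int(c)) for r, c in zip(rows, cols)]

    def is_accessible(self, cell: Cell) -> bool:
        r, c = cell
        h, w = self.occupancy.shape
        return 0 <= r < h and 0 <= c < w and bool(self.occupancy[r, c])

    def is_connected(self) -> bool:
        """True iff accessible cells form one 8-connected component."""
        if self.n_accessible == 0:
            return False
        dist = distance_map(self, self.start_cell)
        return len(dist) == self.n_accessible

    def validate(self, expect_shape: tuple[int, int] | None = (50, 50)) -> None:
        if expect_shape is not None and self.shape != expect_shape:
            raise ValidationError(
                f"lattice is {self.shape}, expected {expect_shape}")
        if not self.is_connected():
            raise ValidationError(
                "accessible cells do not form a single 8-connected component")
        if self.regions:
            union = np.zeros(self.shape, dtype=bool)
            for mask in self.regions.values():
                union |= mask
            if not np.array_equal(union, self.occupancy):
                raise ValidationError("region masks do not tile the occupancy")

    def goal_zone(self, radius: float = 3.0, metric: str = "euclidean") -> np.ndarray:
        """Boolean mask of cells strictly closer than ``radius`` to the goal."""
        rr, cc = np.indices(self.shape)
        dr = rr - self.goal_cell[0]
        dc = cc - self.goal_cell[1]
        if metric == "euclidean":
            d = np.hypot(dr, dc)
        elif metric == "chebyshev":
            d = np.maximum(np.abs(dr), np.abs(dc))
        else:
            raise ConfigurationError(f"unknown goal metric {metric!r}")
        return (d < radius) & self.occupancy

    def arm_of_cell(self, cell: Cell) -> str | None:
        """Region name containing ``cell``, or None."""
        for name, mask in self.regions.items():
            if mask[cell]:
                return name
        return None


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _fixture_dir() -> Path:
    return Path(str(resources.files("escapenav") / "fixtures"))


def read_mask(path: str | Path, chars: str = "1") -> np.ndarray:
    """Read a plain-text lattice mask; True where the char is in ``chars``."""
    lines = Path(path).read_text().strip("\n").split("\n")
    width = len(lines[0])
    if any(len(ln) != width for ln in lines):
        raise ValidationError(f"ragged mask file: {path}")
    return np.array([[ch in chars for ch in ln] for ln in lines], dtype=bool)


def read_region_masks(path: str | Path) -> dict[str, np.ndarray]:
    """Read a letter-coded region mask (chars S/T/L/R, '.' = inaccessible)."""
    lines = Path(path).read_text().strip("\n").split("\n")
    grid = np.array([list(ln) for ln in lines])
    return {name: grid == ch for ch, name in REGION_CHARS.items()}


def build_gridworld(arena_id: int | str,
                    layout_dir: str | Path | None = None) -> GridWorld:
    """Load the packaged grid-world fixture for an arena and validate it.

    ``layout_dir`` overrides the packaged fixture directory (used for custom
    layouts); fixtures consist of ``arena{id}.mask.txt`` (0/1 occupancy),
    ``arena{id}.regions.txt`` (letter-coded regions) and ``arena{id}.yaml``
    (start, goal, arena_id).
    """
    base = Path(layout_dir) if layout_dir is not None else _fixture_dir()
    mask_path = base / f"arena{arena_id}.mask.txt"
    meta_path = base / f"arena{arena_id}.yaml"
    region_path = base / f"arena{arena_id}.regions.txt"
    if not mask_path.exists() or not meta_path.exists():
        raise ConfigurationError(
            f"no grid-world fixture for arena {arena_id!r} in {base}")
    occupancy = read_mask(mask_path)
    meta = yaml.safe_load(meta_path.read_text())
    regions = read_region_masks(region_path) if region_path.exists() else {}
    world = GridWorld(
        occupancy=occupancy,
        start_cell=tuple(meta["start"]),
        goal_cell=tuple(meta["goal"]),
        arena_id=meta.get("arena_id", arena_id),
        regions=regions,
    )
    world.validate(expect_shape=(50, 50))
    return world


def available_fixture_arenas(layout_dir: str | Path | None = None) -> list[int]:
    base = Path(layout_dir) if layout_dir is not None else _fixture_dir()
    ids = []
    for p in sorted(base.glob("arena*.yaml")):
        token = p.stem.removeprefix("arena")
        ids.append(int(token) if token.isdigit() else token)
    return ids


# ---------------------------------------------------------------------------
# Reward function and transition dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardParams:
    """Reward structure shared by all agent classes.

    A reward of ``goal_reward`` is delivered whenever a move ends strictly
    closer than ``goal_radius_cells`` to the goal cell; attempting a move into
    an inaccessible cell leaves the agent in place and costs
    ``illegal_penalty``. The tiny ``novelty_bonus`` is delivered on moves into
    never-visited cells, for the model-free agent class only (it is switched
    on per-agent, not here). Contributions are additive.
    """

    goal_reward: float = REWARD_DEFAULTS["goal_reward"]
    goal_radius_cells: float = REWARD_DEFAULTS["goal_radius_cells"]
    illegal_penalty: float = REWARD_DEFAULTS["illegal_penalty"]
    novelty_bonus: float = REWARD_DEFAULTS["novelty_bonus"]
    goal_metric: str = REWARD_DEFAULTS["goal_metric"]

    def __post_init__(self):
        if self.goal_reward <= 0:
            raise ValidationError("goal_reward must be positive")
        if self.illegal_penalty >= 0:
            raise ValidationError("illegal_penalty must be negative")
        if self.novelty_bonus < 0:
            raise ValidationError("novelty_bonus must be non-negative")


def in_goal_zone(world: GridWorld, cell: Cell, params: RewardParams) -> bool:
    r, c = cell
    gr, gc = world.goal_cell
    if params.goal_metric == "euclidean":
        d = math.hypot(r - gr, c - gc)
    else:
        d = max(abs(r - gr), abs(c - gc))
    return d < params.goal_radius_cells


def step(world: GridWorld, state: Cell, action: Action, params: RewardParams,
         visited: frozenset | set = frozenset(),
         novelty_enabled: bool = False) -> tuple[Cell, float, bool]:
    """One environment transition. Returns ``(next_state, reward, moved)``.

    Moves into inaccessible cells (or off the lattice) leave the agent in
    place and cost the illegal-move penalty. Diagonal moves are allowed
    whenever the destination cell is accessible (corner-cutting permitted).
    """
    if not world.is_accessible(state):
        raise ContractViolationError(f"state {state} is not accessible")
    dr, dc = action.displacement
    target = (state[0] + dr, state[1] + dc)
    if not world.is_accessible(target):
        return state, params.illegal_penalty, False
    reward = 0.0
    if in_goal_zone(world, target, params):
        reward += params.goal_reward
    if novelty_enabled and target not in visited:
        reward += params.novelty_bonus
    return target, reward, True


# ---------------------------------------------------------------------------
# Shortest-path oracle (8-connected BFS, unit step cost)
# ---------------------------------------------------------------------------

def distance_map(world: GridWorld, src: Cell) -> dict[Cell, int]:
    """BFS distances (in moves) from ``src`` to every reachable cell."""
    if not world.is_accessible(src):
        raise ContractViolationError(f"cell {src} is not accessible")
    occ = world.occupancy
    h, w = occ.shape
    dist = {src: 0}
    q = deque([src])
    while q:
        r, c = q.popleft()
        d = dist[(r, c)]
        for dr, dc in ACTION_DISPLACEMENTS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and occ[nr, nc] \
                    and (nr, nc) not in dist:
                dist[(nr, nc)] = d + 1
                q.append((nr, nc))
    return dist


def shortest_path_length(world: GridWorld, src: Cell, dst: Cell) -> float:
    """Length of the shortest 8-connected path through accessible cells.

    Returns 0 iff ``src == dst`` and :data:`UNREACHABLE` (infinity) when no
    path exists.
    """
    if not world.is_accessible(dst):
        raise ContractViolationError(f"cell {dst} is not accessible")
    return distance_map(world, src).get(tuple(dst), UNREACHABLE)


def shortest_path(world: GridWorld, src: Cell, dst: Cell) -> list[Cell]:
    """One shortest 8-connected cell path from ``src`` to ``dst``, inclusive."""
    if not world.is_accessible(dst):
        raise ContractViolationError(f"cell {dst} is not accessible")
    src, dst = tuple(src), tuple(dst)
    if src == dst:
        return [src]
    occ = world.occupancy
    h, w = occ.shape
    prev: dict[Cell, Cell] = {src: src}
    q = deque([src])
    # explore neighbors nearest-to-destination first so that, among equal
    # length paths, the most direct one is reconstructed (a 3-cell
    # horizontal gap decomposes into 3 horizontal moves)
    order = sorted(
        map(tuple, ACTION_DISPLACEMENTS),
        key=lambda d: (math.hypot(src[0] + d[0] - dst[0],
                                  src[1] + d[1] - dst[1])))
    while q:
        r, c = q.popleft()
        for dr, dc in order:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and occ[nr, nc] \
                    and (nr, nc) not in prev:
                prev[(nr, nc)] = (r, c)
                if (nr, nc) == dst:
                    path = [dst]
                    while path[-1] != src:
                        path.append(prev[path[-1]])
                    return path[::-1]
                q.append((nr, nc))
    raise ValidationError(f"{dst} is unreachable from {src}")


def goal_zone_distance(world: GridWorld, params: RewardParams) -> dict[Cell, int]:
    """BFS distance from every cell to the nearest goal-zone cell.

    This is the oracle for policy optimality: an optimal greedy trajectory
    from the start terminates after exactly ``goal_zone_distance[start]``
    moves.
    """
    zone = world.goal_zone(params.goal_radius_cells, params.goal_metric)
    occ = world.occupancy
    h, w = occ.shape
    dist: dict[Cell, int] = {}
    q: deque[Cell] = deque()
    for r, c in zip(*np.nonzero(zone)):
        dist[(int(r), int(c))] = 0
        q.append((int(r), int(c)))
    while q:
        r, c = q.popleft()
        d = dist[(r, c)]
        for dr, dc in ACTION_DISPLACEMENTS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and occ[nr, nc] \
                    and (nr, nc) not in dist:
                dist[(nr, nc)] = d + 1
                q.append((nr, nc))
    return dist


# ---------------------------------------------------------------------------
# Compiled transition tables (fast inner loops)
# ---------------------------------------------------------------------------

class CompiledWorld:
    """Flat-index transition tables for fast training loops.

    Semantics are identical to :func:`step`; the equivalence is covered by
    tests. Cells are flattened as ``r * ncols + c``.
    """

    def __init__(self, world: GridWorld, params: RewardParams | None = None):
        self.world = world
        self.params = params or RewardParams()
        h, w = world.shape
        self.shape = (h, w)
        occ = world.occupancy
        self.accessible_flat = np.flatnonzero(occ.ravel())
        # next_flat[s, a] == -1 encodes an illegal move
        rr, cc = np.indices((h, w))
        nxt = np.full((h * w, len(ACTIONS)), -1, dtype=np.int64)
        for ai, (dr, dc) in enumerate(ACTION_DISPLACEMENTS):
            nr, nc = rr + dr, cc + dc
            ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
            legal = np.zeros((h, w), dtype=bool)
            legal[ok] = occ[nr[ok], nc[ok]]
            tgt = np.where(legal, nr * w + nc, -1)
            nxt[:, ai] = tgt.ravel()
        nxt[~occ.ravel()] = -1
        self.next_flat = nxt
        zone = world.goal_zone(self.params.goal_radius_cells,
                               self.params.goal_metric)
        self.goal_zone_flat = zone.ravel()
        self.goal_reward_flat = np.where(
            self.goal_zone_flat, self.params.goal_reward, 0.0)
        self.start_flat = world.start_cell[0] * w + world.start_cell[1]
        self.goal_flat = world.goal_cell[0] * w + world.goal_cell[1]

    def flat(self, cell: Cell) -> int:
        return cell[0] * self.shape[1] + cell[1]

    def unflat(self, idx: int) -> Cell:
        return divmod(int(idx), self.shape[1])
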