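"""The three reinforcement-learning agent classes.

* :class:`QTableAgent` — model-free tabular Q-learning with temporal-difference
  (TD) updates and a tiny novelty bonus to encourage exploration.
* :class:`DynaQAgent` — DYNA-Q: Q-learning plus a learned deterministic
  transition/reward model replayed offline (20 sampled updates per planning
  step).
* :class:`IZAgent` — Influence Zones: model-based learning on a reduced
  topological map of the environment (an Instantaneous Topological Map, a
  self-organizing incremental graph), with TD errors propagated through node
  neighborhoods.

All agents act over the same 8-action space and reward function; the novelty
bonus applies to the model-free class only. Every stochastic operation takes
an explicit ``numpy.random.Generator``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import (ACTION_DISPLACEMENTS, ACTIONS, Action, Cell,
                    CompiledWorld, GridWorld, RewardParams)
from .config import IZ_DEFAULTS, LEARNING_DEFAULTS, PLANNING_SAMPLES
from .errors import ContractViolationError, ValidationError

_UNIT_DISPLACEMENTS = (ACTION_DISPLACEMENTS
                       / np.linalg.norm(ACTION_DISPLACEMENTS, axis=1,
                                        keepdims=True))


@dataclass(frozen=True)
class LearningParams:
    """Core TD-learning hyperparameters.

    ``epsilon`` is the initial exploration rate; it decays multiplicatively
    by ``epsilon_decay`` at the end of each free-exploration episode.
    """

    alpha: float = LEARNING_DEFAULTS["alpha"]
    gamma: float = LEARNING_DEFAULTS["gamma"]
    epsilon: float = LEARNING_DEFAULTS["epsilon"]
    epsilon_decay: float = LEARNING_DEFAULTS["epsilon_decay"]

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        if not 0 <= self.gamma < 1:
            raise ValidationError("gamma must be in [0, 1)")
        if not 0 <= self.epsilon <= 1:
            raise ValidationError("epsilon must be in [0, 1]")
        if not 0 < self.epsilon_decay <= 1:
            raise ValidationError("epsilon_decay must be in (0, 1]")


@dataclass(frozen=True)
class IZParams:
    """Influence-Zones specific parameters (distances in lattice-cell units)."""

    td_threshold_one_step: float = IZ_DEFAULTS["td_threshold_one_step"]
    td_threshold_n_step: float = IZ_DEFAULTS["td_threshold_n_step"]
    itm_learning_rate: float = IZ_DEFAULTS["itm_learning_rate"]
    itm_max_error: float = IZ_DEFAULTS["itm_max_error"]


# ---------------------------------------------------------------------------
# Model-free Q-learning
# ---------------------------------------------------------------------------

class QTableAgent:
    """Tabular Q-learning over (cell, action) pairs, Q initialized to zero.

    The visited-cell set (for the novelty bonus) persists across episodes
    within one agent. Internally cells are flat lattice indices.
    """

    name = "qtable"
    novelty_enabled = True

    def __init__(self, world: GridWorld | CompiledWorld,
                 params: LearningParams | None = None,
                 reward_params: RewardParams | None = None):
        self.cw = world if isinstance(world, CompiledWorld) \
            else CompiledWorld(world, reward_params)
        self.params = params or LearningParams()
        h, w = self.cw.shape
        self.Q = np.zeros((h * w, len(ACTIONS)))
        self.visited: set[int] = set()

    # -- flat-index fast path ----------------------------------------------

    def begin_episode(self, s: int) -> None:
        self.visited.add(s)

    def learn(self, s: int, a: int, r: float, s2: int,
              terminal: bool = False) -> None:
        """One TD update on Q(s, a).

        ``terminal`` is accepted for interface parity with the map-based
        agent; tabular Q needs no special casing because episodes end on
        goal entry, so action values of absorbing cells never grow and the
        bootstrap term vanishes there by itself.
        """
        p = self.params
        q = self.Q
        q[s, a] += p.alpha * (r + p.gamma * q[s2].max() - q[s, a])

    def greedy(self, s: int) -> int:
        """Greedy action index; ties broken toward the first canonical action."""
        return int(np.argmax(self.Q[s]))

    def action_values(self, s: int) -> np.ndarray:
        return self.Q[s].copy()

    # -- cell-tuple public API ---------------------------------------------

    def q_value(self, cell: Cell, action: Action) -> float:
        return float(self.Q[self.cw.flat(cell), ACTIONS.index(action)])


class DynaQAgent(QTableAgent):
    """DYNA-Q: Q-learning plus planning on a learned deterministic model.

    The model stores every experienced (state, action) -> (reward, next state)
    transition; each planning step replays ``planning_samples`` uniformly
    sampled stored transitions through the same TD rule.
    """

    name = "dynaq"
    novelty_enabled = False

    def __init__(self, world, params=None, reward_params=None,
                 planning_samples: int = PLANNING_SAMPLES):
        super().__init__(world, params, reward_params)
        self.planning_samples = planning_samples
        self._model_index: dict[int, int] = {}   # (s * 8 + a) -> row
        self._ms: list[int] = []
        self._ma: list[int] = []
        self._mr: list[float] = []
        self._ms2: list[int] = []

    @property
    def model_size(self) -> int:
        return len(self._ms)

    def model_entry(self, cell: Cell, action: Action) -> tuple[float, Cell] | None:
        key = self.cw.flat(cell) * len(ACTIONS) + ACTIONS.index(action)
        row = self._model_index.get(key)
        if row is None:
            return None
        return self._mr[row], self.cw.unflat(self._ms2[row])

    def learn(self, s: int, a: int, r: float, s2: int,
              terminal: bool = False) -> None:
        super().learn(s, a, r, s2)
        key = s * len(ACTIONS) + a
        row = self._model_index.get(key)
        if row is None:
            self._model_index[key] = len(self._ms)
            self._ms.append(s)
            self._ma.append(a)
            self._mr.append(r)
            self._ms2.append(s2)
        else:                       # deterministic world: refresh in place
            self._mr[row] = r
            self._ms2[row] = s2

    def plan(self, rng: np.random.Generator) -> None:
        """One planning step: ``planning_samples`` TD updates on uniformly
        sampled stored transitions. No-op while the model is empty."""
        n = len(self._ms)
        if n == 0:
            return
        p = self.params
        q = self.Q
        ms, ma, mr, ms2 = self._ms, self._ma, self._mr, self._ms2
        for i in rng.integers(0, n, size=self.planning_samples):
            s, a, r, s2 = ms[i], ma[i], mr[i], ms2[i]
            q[s, a] += p.alpha * (r + p.gamma * q[s2].max() - q[s, a])


# ---------------------------------------------------------------------------
# Influence Zones over an Instantaneous Topological Map
# ---------------------------------------------------------------------------

class IZAgent:
    """Model-based agent learning node values on a self-organized graph.

    The Instantaneous Topological Map (ITM) is built incrementally from the
    stream of visited positions: the nearest node adapts toward each stimulus,
    nodes are inserted where the map's resolution (``itm_max_error``) is
    exceeded, and edges follow the Delaunay-like Thales-sphere criterion.
    Values live on nodes; each TD update at a node is propagated through its
    graph neighborhood (the "influence zone") with geometrically decaying
    magnitude until the propagated error drops below the n-step threshold.
    """

    name = "iz"
    novelty_enabled = False

    def __init__(self, world: GridWorld | CompiledWorld,
                 params: LearningParams | None = None,
                 reward_params: RewardParams | None = None,
                 iz_params: IZParams | None = None):
        self.cw = world if isinstance(world, CompiledWorld) \
            else CompiledWorld(world, reward_params)
        self.params = params or LearningParams()
        self.izp = iz_params or IZParams()
        cap = 64
        self._pos = np.empty((cap, 2))
        self._val = np.zeros(cap)
        self.n_nodes = 0
        self.edges: list[set[int]] = []
        # movement memory: per-cell bitmasks of actions experienced as legal
        # or as penalized wall attempts, used when translating map moves
        # into lattice moves
        self._legal_moves: dict[int, int] = {}
        self._blocked_moves: dict[int, int] = {}
        self._reward_moves: dict[int, int] = {}

    # -- ITM structure ------------------------------------------------------

    @property
    def node_positions(self) -> np.ndarray:
        return self._pos[:self.n_nodes].copy()

    @property
    def node_values(self) -> np.ndarray:
        return self._val[:self.n_nodes].copy()

    def _grow(self) -> None:
        if self.n_nodes == len(self._pos):
            self._pos = np.concatenate([self._pos, np.empty_like(self._pos)])
            self._val = np.concatenate([self._val, np.zeros_like(self._val)])

    def _add_node(self, x: np.ndarray, value: float = 0.0) -> int:
        self._grow()
        i = self.n_nodes
        self._pos[i] = x
        self._val[i] = value
        self.edges.append(set())
        self.n_nodes += 1
        return i

    def _remove_node(self, i: int) -> None:
        """Swap-delete node ``i``, keeping indices compact."""
        last = self.n_nodes - 1
        for m in self.edges[i]:
            self.edges[m].discard(i)
        if i != last:
            self._pos[i] = self._pos[last]
            self._val[i] = self._val[last]
            self.edges[i] = self.edges[last]
            for m in self.edges[i]:
                self.edges[m].discard(last)
                self.edges[m].add(i)
        self.edges.pop()
        self.n_nodes -= 1

    def _nearest2(self, x: np.ndarray) -> tuple[int, int | None]:
        d2 = ((self._pos[:self.n_nodes] - x) ** 2).sum(axis=1)
        if self.n_nodes == 1:
            return 0, None
        order = np.argpartition(d2, 1)[:2]
        if d2[order[0]] <= d2[order[1]]:
            return int(order[0]), int(order[1])
        return int(order[1]), int(order[0])

    def _map_neighbors(self, n: int) -> list[int]:
        """Graph neighbors of ``n`` reachable in one genuine map move.

        Edges much longer than the map resolution are bootstrap leftovers
        that may cross inaccessible space; they stay in the graph (later
        Thales pruning can remove them) but are ignored by value flow and
        action selection.
        """
        cutoff = 3.0 * self.izp.itm_max_error
        w = self._pos[n]
        return sorted(m for m in self.edges[n]
                      if np.hypot(*(self._pos[m] - w)) <= cutoff)

    def nearest_node(self, x) -> int:
        if self.n_nodes == 0:
            raise ContractViolationError("the topological map is empty")
        d2 = ((self._pos[:self.n_nodes] - np.asarray(x, float)) ** 2).sum(axis=1)
        return int(np.argmin(d2))

    def observe(self, x) -> None:
        """One ITM adaptation step on a visited position (map learning is
        reward-independent and runs during exploration)."""
        x = np.asarray(x, dtype=float)
        if self.n_nodes == 0:
            self._add_node(x)
            return
        if self.n_nodes == 1:
            if np.hypot(*(x - self._pos[0])) > 1e-12:
                self._add_node(x, value=self._val[0])
                self.edges[0].add(1)
                self.edges[1].add(0)
            return
        emax = self.izp.itm_max_error
        n1, n2 = self._nearest2(x)
        # adapt the winner toward the stimulus
        self._pos[n1] += self.izp.itm_learning_rate * (x - self._pos[n1])
        w1, w2 = self._pos[n1], self._pos[n2]
        # connect winner and runner-up
        self.edges[n1].add(n2)
        self.edges[n2].add(n1)
        # prune edges failing the Thales-sphere test; drop orphaned nodes
        drop = []
        for m in list(self.edges[n1]):
            if m == n2:
                continue
            if np.dot(w1 - w2, self._pos[m] - w2) < 0:
                self.edges[n1].discard(m)
                self.edges[m].discard(n1)
                if not self.edges[m]:
                    drop.append(m)
        # node insertion where the map under-resolves the stimulus
        if np.dot(w1 - x, w2 - x) > 0 and np.hypot(*(x - w1)) > emax:
            j = self._add_node(x, value=self._val[n1])
            self.edges[n1].add(j)
            self.edges[j].add(n1)
        # node removal where the map over-resolves
        elif np.hypot(*(w1 - w2)) < 0.5 * emax and self.n_nodes > 2:
            drop.append(n2)
        for m in sorted(set(drop), reverse=True):
            if self.n_nodes > 2 and m < self.n_nodes:
                self._remove_node(m)

    # -- value learning -----------------------------------------------------

    def begin_episode(self, s: int) -> None:
        self.observe(self.cw.unflat(s))

    def learn(self, s: int, a: int, r: float, s2: int,
              terminal: bool = False) -> None:
        """ITM adaptation on the new position, transition-memory update,
        then an influence-zone TD update mapping both cells to their
        nearest nodes."""
        if s2 == s:
            self._blocked_moves[s] = self._blocked_moves.get(s, 0) | (1 << a)
        else:
            self._legal_moves[s] = self._legal_moves.get(s, 0) | (1 << a)
            if r > 0:
                # goal entry lies below the map's spatial resolution (the
                # rewarded cell shares a node with its surroundings), so
                # the final approach is remembered at cell level
                self._reward_moves[s] = self._reward_moves.get(s, 0) | (1 << a)
        self.observe(self.cw.unflat(s2))
        self.update_values(self.cw.unflat(s), r, self.cw.unflat(s2),
                           terminal=terminal)

    def update_values(self, s_cell: Cell, r: float, s2_cell: Cell,
                      terminal: bool = False) -> None:
        if self.n_nodes == 0:
            raise ContractViolationError(
                "topological map is empty: feed positions through observe()/"
                "itm_update() during exploration before value updates")
        p = self.params
        n1 = self.nearest_node(s_cell)
        n2 = self.nearest_node(s2_cell)
        if n1 == n2 and r <= 0.0:
            # Movement (or a penalized illegal attempt) within one node's
            # zone carries no information at the map's spatial resolution;
            # nodes have no action resolution, so bootstrapping here would
            # only decay the node value and corrupt the gradient.
            return
        if terminal:
            # Absorbing goal entry (free-exploration episodes end here):
            # the target is the reward itself. Bootstrapping across an
            # absorbing zone would let the arrival-side corridor nodes
            # pump each other without bound, so whichever arm currently
            # carries the traffic towers over the other — a
            # policy-dependent bistability that can lock agents onto the
            # long arm. In guided training the walk genuinely continues
            # through the zone, so those updates bootstrap as usual.
            delta = r - self._val[n1]
        else:
            # off-policy target: bootstrap on the best-valued node
            # reachable from n1 in one map move (the experienced n2 or any
            # graph neighbor), so node values relax toward the optimality
            # fixed point gamma**hops rather than the behavior-policy
            # values
            boot = self._val[n2]
            if self.edges[n1]:
                boot = max(boot, self._val[sorted(self.edges[n1])].max())
            delta = r + p.gamma * boot - self._val[n1]
        if abs(delta) <= self.izp.td_threshold_one_step:
            return
        self._val[n1] += p.alpha * delta
        # n-step propagation through the node neighborhood: nodes at graph
        # depth d are relaxed toward the discounted source value
        # gamma**d * V(n1) (raise-only, so repeated waves cannot inflate
        # values past the optimality fixed point), and the influence zone
        # extends through a node only while its propagated correction
        # exceeds the n-step threshold. Tying the stopping rule to the
        # correction itself, rather than to the decayed source TD error,
        # lets the value gradient keep spreading into rarely visited parts
        # of the map after the goal region has locally converged.
        v1 = self._val[n1]
        decay = p.gamma
        seen = {n1}
        frontier = self.edges[n1] - seen
        while frontier:
            seen |= frontier
            nxt: set[int] = set()
            for m in frontier:
                gap = decay * v1 - self._val[m]
                if gap > self.izp.td_threshold_n_step:
                    self._val[m] += p.alpha * gap
                    nxt |= self.edges[m]
            frontier = nxt - seen
            decay *= p.gamma
        self._excess_nodes_guard()

    def _excess_nodes_guard(self) -> None:
        # structural invariant: never more nodes than accessible cells
        if self.n_nodes > len(self.cw.accessible_flat):
            raise ValidationError("ITM grew beyond the accessible-cell count")

    # -- action selection ---------------------------------------------------

    def action_values(self, s: int) -> np.ndarray:
        """Score the 8 actions by alignment with the best map move.

        The agent navigates the topological map: among the node nearest to
        its position and that node's graph neighbors, the highest-valued one
        is the movement target (first index on ties), and each lattice action
        is scored by the projection of its unit displacement onto the
        direction toward the target node — translating moves in the map into
        moves in cell space. A zero direction (already at a local value
        maximum) scores all actions equally.
        """
        if self.n_nodes == 0:
            return np.zeros(len(ACTIONS))
        pos = np.array(self.cw.unflat(s), dtype=float)
        n = self.nearest_node(pos)
        one_hop = self._map_neighbors(n)
        cands = dict.fromkeys([n, *one_hop])
        for m in one_hop:                      # two map moves of lookahead
            cands.update(dict.fromkeys(self._map_neighbors(m)))
        cands = list(cands)
        vals = self._val[cands]
        target = cands[int(np.argmax(vals))]
        direction = self._pos[target] - pos
        norm = np.hypot(*direction)
        if norm < 1e-12:
            scores = np.zeros(len(ACTIONS))
        else:
            scores = _UNIT_DISPLACEMENTS @ (direction / norm)
        # bias the translation by movement memory: never repeat a known wall
        # attempt, and prefer moves experienced as legal over untried ones
        blocked = self._blocked_moves.get(s, 0)
        legal = self._legal_moves.get(s, 0)
        rewarding = self._reward_moves.get(s, 0)
        for i in range(len(ACTIONS)):
            if rewarding >> i & 1:
                scores[i] += 3.0
            elif blocked >> i & 1:
                scores[i] -= 2.0
            elif not legal >> i & 1:
                scores[i] -= 0.5
        return scores

    def greedy(self, s: int) -> int:
        return int(np.argmax(self.action_values(s)))


MODEL_CLASSES = {cls.name: cls for cls in (QTableAgent, DynaQAgent, IZAgent)}


# ---------------------------------------------------------------------------
# Operation-level public API (cell-tuple signatures)
# ---------------------------------------------------------------------------

def td_update(agent: QTableAgent, s: Cell, a: Action, r: float, s2: Cell) -> QTableAgent:
    """Apply one TD update: Q(s,a) += alpha * (r + gamma max_a' Q(s2,a') - Q(s,a))."""
    for cell in (s, s2):
        if not agent.cw.world.is_accessible(cell):
            raise ContractViolationError(f"cell {cell} is not accessible")
    agent.learn(agent.cw.flat(s), ACTIONS.index(a), r, agent.cw.flat(s2))
    return agent


def dyna_planning(agent: DynaQAgent, rng: np.random.Generator) -> DynaQAgent:
    """Run one DYNA-Q planning step (20 sampled model replays by default)."""
    agent.plan(rng)
    return agent


def itm_update(agent: IZAgent, position) -> IZAgent:
    """Adapt the topological map to one observed continuous position."""
    agent.observe(position)
    return agent


def iz_update(agent: IZAgent, s: Cell, a: Action, r: float, s2: Cell) -> IZAgent:
    """Influence-zone value update for an experienced transition."""
    agent.update_values(s, r, s2)
    return agent


def greedy_action(agent, s: Cell) -> Action:
    """Deterministic greedy action at a cell (ties -> first canonical action)."""
    if not agent.cw.world.is_accessible(s):
        raise ContractViolationError(f"cell {s} is not accessible")
    return ACTIONS[agent.greedy(agent.cw.flat(s))]


def epsilon_greedy_action(agent, s: Cell, epsilon: float,
                          rng: np.random.Generator) -> Action:
    """With probability ``epsilon`` a uniformly random action, else greedy."""
    if rng.random() < epsilon:
        return ACTIONS[int(rng.integers(len(ACTIONS)))]
    return greedy_action(agent, s)
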