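"""Training regimes: free epsilon-greedy exploration and trajectory-guided
exploration, with greedy evaluation and performance quantification.

Free exploration trains each agent for 250 episodes of at most 500 steps,
starting every episode at a random accessible cell; after each episode the
agent is evaluated greedily from the threat-platform start cell without
learning. Guided exploration forces the agent's actions to follow a recorded
(or synthetic) mouse cell path for a single pass, then evaluates greedily.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .agents import MODEL_CLASSES, IZAgent, IZParams, LearningParams
from .arena import (ACTIONS, Action, Cell, CompiledWorld, GridWorld,
                    RewardParams, action_from_displacement, shortest_path)
from .config import GUIDED_DEFAULTS, TRAINING_DEFAULTS
from .errors import (ConfigurationError, ContractViolationError,
                     ValidationError)


class FailureReason(str, Enum):
    NONE = "none"
    TIMEOUT = "timeout"
    ILLEGAL_MOVE = "illegal_move"


@dataclass(frozen=True)
class EpisodeOutcome:
    success: bool
    steps_taken: int
    failure_reason: FailureReason = FailureReason.NONE

    def __post_init__(self):
        if self.success and self.failure_reason is not FailureReason.NONE:
            raise ValidationError("successful episodes carry no failure reason")


@dataclass
class GreedyEvaluation:
    """Result of one no-exploration test run from the start cell."""

    outcome: EpisodeOutcome
    trajectory: list[Cell]
    chosen_arm: str          # 'left' | 'right' | 'none'


@dataclass
class LearningCurve:
    """Per-episode success across repetitions, with mean +/- SEM and a
    rolling-mean smoothed variant (window 6 episodes)."""

    outcomes: np.ndarray      # (n_reps, n_episodes) of 0/1
    mean: np.ndarray
    sem: np.ndarray
    smoothed: np.ndarray
    window: int

    @classmethod
    def from_outcomes(cls, outcomes: np.ndarray,
                      window: int = TRAINING_DEFAULTS["smoothing_window"]):
        outcomes = np.atleast_2d(np.asarray(outcomes, dtype=float))
        n = outcomes.shape[0]
        mean = outcomes.mean(axis=0)
        sd = outcomes.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
        sem = sd / np.sqrt(n)
        smoothed = (pd.Series(mean).rolling(window, min_periods=1)
                    .mean().to_numpy())
        return cls(outcomes=outcomes, mean=mean, sem=sem,
                   smoothed=smoothed, window=window)

    def episodes_to_level(self, level: float = 0.8) -> int | None:
        """First episode index at which the smoothed success rate reaches
        ``level`` (None if never)."""
        idx = np.nonzero(self.smoothed >= level)[0]
        return int(idx[0]) if idx.size else None


def _resolve_model_class(model_class):
    if isinstance(model_class, str):
        try:
            return MODEL_CLASSES[model_class]
        except KeyError:
            raise ConfigurationError(
                f"unknown model class {model_class!r}; "
                f"choose from {sorted(MODEL_CLASSES)}")
    if model_class in MODEL_CLASSES.values():
        return model_class
    raise ConfigurationError(f"unknown model class {model_class!r}")


def _chosen_arm(trajectory, world: GridWorld) -> str:
    """First arm region entered along a trajectory ('none' if neither)."""
    left = world.regions.get("left_arm")
    right = world.regions.get("right_arm")
    if left is None or right is None:
        return "none"
    for cell in trajectory:
        if left[cell]:
            return "left"
        if right[cell]:
            return "right"
    return "none"


# ---------------------------------------------------------------------------
# Greedy evaluation
# ---------------------------------------------------------------------------

def evaluate_greedy(agent, world: GridWorld | None = None,
                    max_steps: int = TRAINING_DEFAULTS["max_steps"]) -> GreedyEvaluation:
    """Run the agent greedily from the start cell without learning.

    Success iff the goal zone is reached within ``max_steps``; an attempted
    illegal move terminates the run as a failure. Never mutates the agent.
    """
    cw: CompiledWorld = agent.cw
    world = world if world is not None else cw.world
    s = cw.start_flat
    trajectory = [cw.unflat(s)]
    if cw.goal_zone_flat[s]:
        return GreedyEvaluation(EpisodeOutcome(True, 0), trajectory,
                                _chosen_arm(trajectory, world))
    nxt_table = cw.next_flat
    zone = cw.goal_zone_flat
    for t in range(max_steps):
        a = agent.greedy(s)
        nxt = nxt_table[s, a]
        if nxt < 0:
            return GreedyEvaluation(
                EpisodeOutcome(False, t + 1, FailureReason.ILLEGAL_MOVE),
                trajectory, _chosen_arm(trajectory, world))
        s = int(nxt)
        trajectory.append(cw.unflat(s))
        if zone[s]:
            return GreedyEvaluation(EpisodeOutcome(True, t + 1), trajectory,
                                    _chosen_arm(trajectory, world))
    return GreedyEvaluation(
        EpisodeOutcome(False, max_steps, FailureReason.TIMEOUT),
        trajectory, _chosen_arm(trajectory, world))


# ---------------------------------------------------------------------------
# Free exploration
# ---------------------------------------------------------------------------

@dataclass
class FreeExplorationResult:
    model: str
    curve: LearningCurve
    final_evaluations: list[GreedyEvaluation]
    training_arms: np.ndarray      # (n_reps, n_episodes): 0 none, 1 left, 2 right
    agents: list = field(repr=False, default_factory=list)

    @property
    def final_success_rate(self) -> float:
        return float(np.mean([e.outcome.success for e in self.final_evaluations]))

    def short_arm_fraction(self, short_arm: str = "right") -> float | None:
        """Fraction of goal-reaching final evaluations taking the short arm."""
        arms = [e.chosen_arm for e in self.final_evaluations if e.outcome.success]
        if not arms:
            return None
        return float(np.mean([a == short_arm for a in arms]))


_ARM_CODE = {"none": 0, "left": 1, "right": 2}


def run_free_exploration(model_class, world: GridWorld,
                         params: LearningParams | None = None,
                         reward_params: RewardParams | None = None,
                         iz_params: IZParams | None = None,
                         n_episodes: int = TRAINING_DEFAULTS["n_episodes"],
                         max_steps: int = TRAINING_DEFAULTS["max_steps"],
                         n_reps: int = TRAINING_DEFAULTS["n_reps"],
                         seed: int = 0,
                         keep_agents: bool = True) -> FreeExplorationResult:
    """Train ``n_reps`` independent agents under epsilon-greedy exploration.

    Each episode starts at a uniformly random accessible cell outside the
    goal zone and ends on goal-zone entry or after ``max_steps`` steps; the
    exploration rate decays multiplicatively after each episode. After every
    episode the agent is evaluated greedily from the start cell (experience
    from the evaluation is never used for learning).
    """
    cls = _resolve_model_class(model_class)
    params = params or LearningParams()
    cw = CompiledWorld(world, reward_params)
    rp = cw.params
    start_pool = np.array(
        [s for s in cw.accessible_flat if not cw.goal_zone_flat[s]],
        dtype=np.int64)
    outcomes = np.zeros((n_reps, n_episodes), dtype=np.int8)
    training_arms = np.zeros((n_reps, n_episodes), dtype=np.int8)
    agents, final_evals = [], []
    children = np.random.SeedSequence(seed).spawn(n_reps)
    nxt_table, zone, goal_r = cw.next_flat, cw.goal_zone_flat, cw.goal_reward_flat
    penalty, bonus = rp.illegal_penalty, rp.novelty_bonus
    n_actions = len(ACTIONS)
    for rep in range(n_reps):
        rng = np.random.default_rng(children[rep])
        kwargs = {"iz_params": iz_params} if cls is IZAgent and iz_params else {}
        agent = cls(cw, params, **kwargs)
        is_dyna = hasattr(agent, "plan")
        novelty = agent.novelty_enabled
        eps = params.epsilon
        for ep in range(n_episodes):
            s = int(start_pool[rng.integers(len(start_pool))])
            agent.begin_episode(s)
            u = rng.random(max_steps)
            ra = rng.integers(0, n_actions, size=max_steps)
            for t in range(max_steps):
                a = int(ra[t]) if u[t] < eps else agent.greedy(s)
                nxt = nxt_table[s, a]
                if nxt < 0:
                    r, s2, done = penalty, s, False
                else:
                    s2 = int(nxt)
                    r = goal_r[s2]
                    done = bool(zone[s2])        # goal entry ends the episode
                    if novelty and s2 not in agent.visited:
                        r += bonus
                        agent.visited.add(s2)
                agent.learn(s, a, r, s2, terminal=done)
                if is_dyna:
                    agent.plan(rng)
                s = s2
                if done:
                    break
            eps *= params.epsilon_decay
            ev = evaluate_greedy(agent, world, max_steps=max_steps)
            outcomes[rep, ep] = ev.outcome.success
            training_arms[rep, ep] = _ARM_CODE[ev.chosen_arm]
            if ep == n_episodes - 1:
                final_evals.append(ev)
        if keep_agents:
            agents.append(agent)
    return FreeExplorationResult(
        model=cls.name, curve=LearningCurve.from_outcomes(outcomes),
        final_evaluations=final_evals, training_arms=training_arms,
        agents=agents)


# ---------------------------------------------------------------------------
# Guided exploration
# ---------------------------------------------------------------------------

def action_from_transition(cell_a: Cell, cell_b: Cell,
                           world: GridWorld | None = None):
    """Action(s) leading from ``cell_a`` to ``cell_b``.

    For 8-neighbor pairs, returns the single :class:`Action`. For larger
    separations (tracking gaps) a ``world`` is required and the gap is
    decomposed into unit actions along a BFS shortest path; a list of actions
    is returned. Identical cells violate the contract (stationary frames must
    already be removed).
    """
    if tuple(cell_a) == tuple(cell_b):
        raise ContractViolationError(
            f"identical consecutive cells {cell_a}: stationary frames "
            "must be removed before guided training")
    dr, dc = cell_b[0] - cell_a[0], cell_b[1] - cell_a[1]
    if max(abs(dr), abs(dc)) == 1:
        return action_from_displacement(dr, dc)
    if world is None:
        raise ContractViolationError(
            f"cells {cell_a} and {cell_b} are not 8-neighbors and no world "
            "was given to apply the gap policy")
    path = shortest_path(world, tuple(cell_a), tuple(cell_b))
    return [action_from_displacement(b[0] - a[0], b[1] - a[1])
            for a, b in zip(path, path[1:])]


def expand_cell_path(world: GridWorld, cells) -> list[Cell]:
    """Insert BFS shortest-path cells into any non-adjacent consecutive pair
    so the result is a chain of unit 8-neighbor moves."""
    cells = [tuple(c) for c in cells]
    for i, cell in enumerate(cells):
        if not world.is_accessible(cell):
            raise ValidationError(
                f"cell path contains inaccessible cell {cell} at index {i}")
    out = [cells[0]]
    for a, b in zip(cells, cells[1:]):
        if a == b:
            raise ContractViolationError(
                f"identical consecutive cells {a} in cell path")
        if max(abs(b[0] - a[0]), abs(b[1] - a[1])) == 1:
            out.append(b)
        else:
            out.extend(shortest_path(world, a, b)[1:])
    return out


@dataclass
class GuidedSessionResult:
    model: str
    evaluations: list[GreedyEvaluation]
    success: bool                  # >= 8/10 repetitions reached the goal
    n_success: int
    chosen_arm: str                # modal arm among successful repetitions

    @property
    def success_fraction(self) -> float:
        return self.n_success / len(self.evaluations)


def run_guided(model_class, cell_path, world: GridWorld,
               params: LearningParams | None = None,
               reward_params: RewardParams | None = None,
               iz_params: IZParams | None = None,
               n_reps: int = GUIDED_DEFAULTS["n_reps"],
               success_threshold: int = GUIDED_DEFAULTS["success_threshold"],
               max_steps: int = TRAINING_DEFAULTS["max_steps"],
               seed: int = 0) -> GuidedSessionResult:
    """Train agents whose actions are forced to follow a recorded cell path.

    The agent starts at the first path cell; for each consecutive pair the
    forced action is performed, rewards are experienced, and the agent learns
    exactly as in free exploration (one single pass). Training is fully
    deterministic for the Q-table and IZ classes; only DYNA-Q's planning
    sampler consumes randomness. Afterwards each repetition is evaluated
    greedily from the start cell; the session is successful if at least
    ``success_threshold`` of ``n_reps`` repetitions reach the goal.
    """
    cls = _resolve_model_class(model_class)
    params = params or LearningParams()
    cw = CompiledWorld(world, reward_params)
    raw = getattr(cell_path, "cells", cell_path)
    steps = expand_cell_path(world, raw)
    flat_steps = [cw.flat(c) for c in steps]
    zone, goal_r = cw.goal_zone_flat, cw.goal_reward_flat
    children = np.random.SeedSequence(seed).spawn(n_reps)
    evaluations = []
    for rep in range(n_reps):
        rng = np.random.default_rng(children[rep])
        kwargs = {"iz_params": iz_params} if cls is IZAgent and iz_params else {}
        agent = cls(cw, params, **kwargs)
        is_dyna = hasattr(agent, "plan")
        s = flat_steps[0]
        agent.begin_episode(s)
        for s2 in flat_steps[1:]:
            a = _flat_action(cw, s, s2)
            # the novelty bonus is an exploration-shaping device; with
            # forced actions it shapes nothing, so it is not delivered here
            r = goal_r[s2]
            agent.learn(s, a, r, s2)
            if is_dyna:
                agent.plan(rng)
            s = s2
        evaluations.append(evaluate_greedy(agent, world, max_steps=max_steps))
    n_success = sum(e.outcome.success for e in evaluations)
    arms = [e.chosen_arm for e in evaluations if e.outcome.success]
    chosen = max(set(arms), key=arms.count) if arms else "none"
    return GuidedSessionResult(model=cls.name, evaluations=evaluations,
                               success=n_success >= success_threshold,
                               n_success=n_success, chosen_arm=chosen)


def _flat_action(cw: CompiledWorld, s: int, s2: int) -> int:
    w = cw.shape[1]
    dr = s2 // w - s // w
    dc = s2 % w - s % w
    return ACTIONS.index(action_from_displacement(dr, dc))


# ---------------------------------------------------------------------------
# Performance quantification
# ---------------------------------------------------------------------------

@dataclass
class PerformanceSummary:
    accuracy_mean: float
    accuracy_sem: float
    short_arm_fraction: float | None
    curve: LearningCurve | None


def summarize_performance(outcomes, short_arm: str = "right",
                          window: int = TRAINING_DEFAULTS["smoothing_window"]
                          ) -> PerformanceSummary:
    """Aggregate evaluation outcomes.

    ``outcomes`` is either a 2-D (repetitions x episodes) 0/1 array — in
    which case the smoothed learning curve is computed and the accuracy
    refers to the final episode — or a flat sequence of
    :class:`GreedyEvaluation` (accuracy across repetitions plus the fraction
    of successes taking the short arm).
    """
    if (hasattr(outcomes, "__len__") and len(outcomes) == 0) or outcomes is None:
        raise ValidationError("summarize_performance needs at least one outcome")
    if isinstance(outcomes, np.ndarray) and outcomes.ndim == 2:
        curve = LearningCurve.from_outcomes(outcomes, window=window)
        return PerformanceSummary(float(curve.mean[-1]), float(curve.sem[-1]),
                                  None, curve)
    evals = list(outcomes)
    if isinstance(evals[0], GreedyEvaluation):
        succ = np.array([e.outcome.success for e in evals], dtype=float)
        arms = [e.chosen_arm for e in evals if e.outcome.success]
        frac = float(np.mean([a == short_arm for a in arms])) if arms else None
    else:
        succ = np.asarray(evals, dtype=float)
        frac = None
    n = len(succ)
    sem = float(succ.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return PerformanceSummary(float(succ.mean()), sem, frac, None)


def visit_count_matrix(trajectories, shape: tuple[int, int]) -> np.ndarray:
    """Total visits per cell across trajectories (occupancy heatmap data)."""
    counts = np.zeros(shape, dtype=np.int64)
    for traj in trajectories:
        for cell in traj:
            counts[cell] += 1
    return counts
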