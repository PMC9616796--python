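"""Synthetic data generators.

Produce tracking sessions, trial tables and GLM datasets with the
statistical structure the analysis pipeline assumes, so every stage is
testable without the deposited experimental data. Sessions emulate natural
exploration: piecemeal back-and-forth sampling of both arms, a handful of
complete shelter<->threat round trips, and a cell-path length drawn around
754 +/- 267 state changes. All generators are deterministic under a fixed
seed and return their ground truth for round-trip tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import ARENA_SPECS, Cell, GridWorld, shortest_path
from .config import CM_PER_CELL
from .errors import ValidationError
from .trajectory import BODYPARTS, CellPath, TrackingData, Trip


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSessionSpec:
    """Parameters of one synthetic exploration session.

    Defaults reproduce the study conditions: 2-3 round trips (4-6 one-way
    trips), a target cell-path length drawn from Normal(754, 267) truncated
    above 100 state changes, 30 or 40 fps video, and centimetre-scale
    tracking jitter. ``n_trips`` counts round trips (each contributes one
    shelter-to-threat and one threat-to-shelter trip). When ``noise_sd`` is
    zero the rendered positions are exact cell centers and the low-confidence
    dropout corruption is disabled (the noise-free setting used for
    round-trip validation).
    """

    arena_id: int | str = 4
    n_trips: int | None = None
    target_state_changes: int | None = None
    fps: float = 30.0
    noise_sd: float = 0.5              # cm
    dropout_rate: float = 0.02         # low-likelihood corrupted frames
    move_dwell_frames: int = 4         # frames spent per cell along a move
    platform_dwell_frames: int = 40    # extra dwell on platform arrivals
    walk_bias: float = 0.9             # P(step toward the current waypoint);
    # the remainder are uniform local steps. Mice move in persistent bouts,
    # so de-duplicated cell paths at ~12 cm cell scale rarely backtrack.
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_trips is not None and self.n_trips <= 0:
            raise ValidationError("n_trips must be positive")
        if self.target_state_changes is not None \
                and self.target_state_changes <= 0:
            raise ValidationError("target_state_changes must be positive")


@dataclass
class SyntheticSession:
    tracking: TrackingData
    cell_path: CellPath                # ground truth
    trips: list[Trip]                  # ground truth
    spec: SyntheticSessionSpec
    stimulus_frame: int | None = None


def _arm_routes(world: GridWorld) -> dict[str, list[Cell]]:
    """Start-to-goal cell routes confined to each arm (platforms included)."""
    routes = {}
    for arm in ("left_arm", "right_arm"):
        other = "right_arm" if arm == "left_arm" else "left_arm"
        occ = world.occupancy & ~world.regions[other]
        sub = GridWorld(occ, world.start_cell, world.goal_cell,
                        world.arena_id, regions={})
        routes[arm] = shortest_path(sub, world.start_cell, world.goal_cell)
    return routes


def _platform_wiggle(world: GridWorld, cell: Cell, region: str,
                     rng: np.random.Generator | None = None) -> Cell:
    """An adjacent cell within the same platform region (for 1-change pads)."""
    mask = world.regions[region]
    cands = []
    for dr in (0, -1, 1):
        for dc in (0, -1, 1):
            if dr == dc == 0:
                continue
            cand = (cell[0] + dr, cell[1] + dc)
            if world.is_accessible(cand) and mask[cand]:
                cands.append(cand)
    if not cands:
        raise ValidationError(f"no wiggle room on platform {region}")
    if rng is None:
        return cands[0]
    return cands[int(rng.integers(len(cands)))]


def _region_distance_map(world: GridWorld, goal_cells: set[Cell],
                         blocked: np.ndarray | None) -> dict[Cell, int]:
    from collections import deque
    occ = world.occupancy if blocked is None else world.occupancy & ~blocked
    dist: dict[Cell, int] = {}
    q: deque[Cell] = deque()
    for cell in goal_cells:
        dist[cell] = 0
        q.append(cell)
    h, w = occ.shape
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                p = (r + dr, c + dc)
                if 0 <= p[0] < h and 0 <= p[1] < w and occ[p] \
                        and p not in dist:
                    dist[p] = dist[(r, c)] + 1
                    q.append(p)
    return dist


def _biased_walk(world: GridWorld, start: Cell, goal_cells: set[Cell],
                 rng: np.random.Generator, bias: float = 0.8,
                 blocked: np.ndarray | None = None,
                 max_steps: int = 2000) -> list[Cell]:
    """A goal-directed persistent random walk, excluding the start cell.

    With probability ``bias`` each step moves along a shortest route toward
    the goal region; otherwise a uniformly random accessible neighbor is
    taken (producing the local reversals and dithering seen in natural
    exploration). ``blocked`` cells are never entered.
    """
    dist = _region_distance_map(world, goal_cells, blocked)
    if start not in dist:
        raise ValidationError("goal region unreachable from start")
    path: list[Cell] = []
    cur = start
    for _ in range(max_steps):
        if cur in goal_cells:
            return path
        nbrs = []
        toward = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                p = (cur[0] + dr, cur[1] + dc)
                if p in dist:
                    nbrs.append(p)
                    if dist[p] == dist[cur] - 1:
                        toward.append(p)
        if rng.random() < bias and toward:
            cur = toward[int(rng.integers(len(toward)))]
        else:
            cur = nbrs[int(rng.integers(len(nbrs)))]
        path.append(cur)
    raise ValidationError("biased walk failed to reach its goal region")


def plan_cell_sequence(spec: SyntheticSessionSpec, world: GridWorld,
                       rng: np.random.Generator
                       ) -> tuple[list[Cell], list[int], int]:
    """Plan the ground-truth cell sequence as scheduled persistent walks.

    The session starts on the shelter platform and completes ``n_trips``
    round trips, each leg executed as a biased random walk (local reversals
    and dithering included) along a randomly chosen arm. Before each trip
    leg, incomplete out-and-back excursions into the arms emulate the
    piecemeal sampling of the environment; the far platform is never touched
    during an excursion, so trip ground truth is exact. Platform "milling"
    steps pad the sequence to exactly the target state-change count.

    Returns the de-duplicated cell sequence, the indices of leg boundaries,
    and the number of round trips.
    """
    n_trips = spec.n_trips if spec.n_trips is not None \
        else int(rng.integers(2, 4))                    # 2-3 round trips
    target = spec.target_state_changes
    drawn = target is None
    if drawn:
        target = max(101, int(round(rng.normal(754.0, 267.0))))
    arms = ("left_arm", "right_arm")
    routes = _arm_routes(world)
    shelter_cells = {tuple(map(int, rc))
                     for rc in zip(*np.nonzero(world.regions["shelter"]))}
    threat_cells = {tuple(map(int, rc))
                    for rc in zip(*np.nonzero(world.regions["threat"]))}
    platform_cells = {"shelter": shelter_cells, "threat": threat_cells}
    platform_mask = {"shelter": world.regions["shelter"],
                     "threat": world.regions["threat"]}

    def excursion(cur: Cell, here: str, max_cost: int) -> list[Cell]:
        """Out-and-back walk into a random arm, far platform blocked."""
        far = "threat" if here == "shelter" else "shelter"
        arm = arms[rng.integers(2)]
        route = routes[arm] if here == "threat" else routes[arm][::-1]
        # a depth-k excursion costs about 2k * 4/3 state changes
        cap = min(len(route) - 3, max(4, max_cost // 4))
        depth = int(rng.integers(3, max(4, cap)))
        turnaround = {route[depth]}
        out = _biased_walk(world, cur, turnaround, rng,
                           bias=spec.walk_bias, blocked=platform_mask[far])
        back = _biased_walk(world, out[-1], platform_cells[here], rng,
                            bias=spec.walk_bias, blocked=platform_mask[far])
        return out + back

    def trip_leg(cur: Cell, here: str) -> tuple[list[Cell], str]:
        dest = "threat" if here == "shelter" else "shelter"
        arm = arms[rng.integers(2)]
        blocked = ~world.regions[arm] & ~world.regions[dest] \
            & ~world.regions[here]
        walk = _biased_walk(world, cur, platform_cells[dest], rng,
                            bias=spec.walk_bias, blocked=blocked)
        return walk, dest

    # a persistent walk covers roughly 4/3 of the geodesic; keep a generous
    # reserve so the scheduled trips always fit inside the budget
    max_leg = max(len(r) for r in routes.values())
    reserve_per_leg = int(2.2 * max_leg) + 20

    flat: list[Cell] = [world.goal_cell]                # start at shelter
    boundaries = [0]
    here = "shelter"
    legs_remaining = 2 * n_trips
    while True:
        budget = target - (len(flat) - 1)
        reserve = legs_remaining * reserve_per_leg
        if legs_remaining > 0 and budget <= reserve:
            walk, here = trip_leg(flat[-1], here)
            flat.extend(walk)
            legs_remaining -= 1
        elif budget > reserve + 40 and (legs_remaining == 0
                                        or rng.random() < 0.6):
            flat.extend(excursion(flat[-1], here, budget - reserve - 20))
        elif legs_remaining > 0:
            walk, here = trip_leg(flat[-1], here)
            flat.extend(walk)
            legs_remaining -= 1
        else:
            break
        boundaries.append(len(flat) - 1)
    # mill about on the final platform up to the exact target count
    while len(flat) - 1 < target:
        flat.append(_platform_wiggle(world, flat[-1], here, rng))
    if spec.target_state_changes is not None and len(flat) - 1 > target:
        raise ValidationError(
            f"target_state_changes={target} too small for {n_trips} round "
            f"trips (the walk needed {len(flat) - 1} state changes)")
    return flat, boundaries, n_trips


def render_frames(cells: list[Cell], spec: SyntheticSessionSpec,
                  world: GridWorld, rng: np.random.Generator
                  ) -> TrackingData:
    """Render a cell sequence to frame-level bodypart tracking.

    Each state change spans ``move_dwell_frames`` frames interpolated
    between cell centers; platform arrivals add a longer dwell. Bodyparts
    are offset along the instantaneous heading, Gaussian jitter of
    ``noise_sd`` cm is added, likelihoods follow Beta(50, 1), and (when
    noise is enabled) a fraction of frames is corrupted and marked with a
    low likelihood to exercise the confidence filter.
    """
    platforms = world.regions.get("shelter", np.zeros(world.shape, bool)) | \
        world.regions.get("threat", np.zeros(world.shape, bool))
    pts: list[np.ndarray] = []
    centers = [np.array([c, r], dtype=float) for r, c in cells]  # (x, y)
    for i, center in enumerate(centers):
        if i == 0:
            pts.append(center)
        else:
            prev = centers[i - 1]
            for f in range(1, spec.move_dwell_frames + 1):
                frac = f / spec.move_dwell_frames
                if abs(frac - 0.5) < 1e-9:
                    # the exact midpoint of a diagonal move is equidistant
                    # from four cells; nudge it toward the destination so
                    # noise-free rendering snaps back to the planned path
                    frac += 0.25 / spec.move_dwell_frames
                pts.append(prev + frac * (center - prev))
        r, c = cells[i]
        if platforms[r, c] and i not in (0,) and spec.platform_dwell_frames:
            arriving_platform = (i == len(cells) - 1
                                 or not platforms[cells[i + 1]])
            if arriving_platform:
                pts.extend([center] * spec.platform_dwell_frames)
    P = np.array(pts)
    n = len(P)
    # headings from motion (cm scale used for bodypart offsets)
    deltas = np.gradient(P, axis=0)
    norms = np.linalg.norm(deltas, axis=1, keepdims=True)
    heads = np.divide(deltas, norms, out=np.zeros_like(deltas),
                      where=norms > 1e-9)
    offsets_cm = {"snout": 4.0, "neck": 2.0, "body": 0.0, "tail_base": -4.0}
    noise_cells = spec.noise_sd / CM_PER_CELL
    cols = {}
    corrupt = np.zeros(n, dtype=bool)
    if spec.noise_sd > 0 and spec.dropout_rate > 0:
        corrupt = rng.random(n) < spec.dropout_rate
    for bp in BODYPARTS:
        xy = P + heads * (offsets_cm[bp] / CM_PER_CELL)
        if spec.noise_sd > 0:
            xy = xy + rng.normal(0.0, noise_cells, size=xy.shape)
        lik = rng.beta(50.0, 1.0, size=n)
        if corrupt.any():
            xy[corrupt] += rng.normal(0.0, 8.0 / CM_PER_CELL,
                                      size=(int(corrupt.sum()), 2))
            lik[corrupt] = rng.uniform(0.0, 0.9, size=int(corrupt.sum()))
        cols[(bp, "x")] = xy[:, 0]
        cols[(bp, "y")] = xy[:, 1]
        cols[(bp, "likelihood")] = lik
    frames = pd.DataFrame(cols)
    frames.columns = pd.MultiIndex.from_tuples(frames.columns)
    frames.index.name = "frame"
    return TrackingData(frames, fps=spec.fps)


def generate_session(spec: SyntheticSessionSpec, world: GridWorld
                     ) -> SyntheticSession:
    """Generate one synthetic exploration session with ground truth."""
    rng = np.random.default_rng(spec.seed)
    cells, _, n_trips = plan_cell_sequence(spec, world, rng)
    tracking = render_frames(cells, spec, world, rng)
    path = CellPath(cells, session_id=f"synthetic-{spec.seed}")
    # ground-truth trips from the rendered frames (exact frame indices)
    from .trajectory import segment_trips
    trips = segment_trips(tracking, world)
    if len(trips) != 2 * n_trips:
        raise ValidationError(
            f"internal: planned {2 * n_trips} trips, rendered {len(trips)}")
    return SyntheticSession(tracking, path, trips, spec)


# ---------------------------------------------------------------------------
# Escape-trial generation (frame-level, for classifier tests)
# ---------------------------------------------------------------------------

def generate_escape_trial(world: GridWorld, *, arm: str = "right",
                          leave_s: float = 2.5, speed_cm_s: float = 50.0,
                          shelter_s: float | None = None, fps: float = 30.0,
                          pre_s: float = 1.0, total_s: float = 12.0,
                          seed: int = 0) -> tuple[TrackingData, int]:
    """Synthesize a post-stimulus trial with programmed exit time and speed.

    The mouse sits on the threat platform, leaves it ``leave_s`` seconds
    after the stimulus at ``speed_cm_s`` along the ``arm`` route, and (if it
    reaches it) stays at the shelter. Returns the tracking data and the
    stimulus frame index.
    """
    rng = np.random.default_rng(seed)
    route = _arm_routes(world)[f"{arm}_arm"]             # threat -> shelter
    centers = np.array([(c, r) for r, c in route], dtype=float)
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])        # cells
    stim = int(round(pre_s * fps))
    n = int(round(total_s * fps)) + stim
    speed_cells = speed_cm_s / CM_PER_CELL
    pts = np.empty((n, 2))
    for i in range(n):
        t = (i - stim) / fps
        dist = max(0.0, (t - leave_s)) * speed_cells
        dist = min(dist, cum[-1])
        j = int(np.searchsorted(cum, dist, side="right") - 1)
        if j >= len(seg):
            pts[i] = centers[-1]
        else:
            frac = (dist - cum[j]) / seg[j]
            pts[i] = centers[j] + frac * (centers[j + 1] - centers[j])
    cols = {}
    for bp in BODYPARTS:
        off = {"snout": 0.3, "neck": 0.15, "body": 0.0, "tail_base": -0.3}[bp]
        xy = pts + np.array([0.0, -off])
        cols[(bp, "x")] = xy[:, 0]
        cols[(bp, "y")] = xy[:, 1]
        cols[(bp, "likelihood")] = rng.beta(50, 1, size=n)
    frames = pd.DataFrame(cols)
    frames.columns = pd.MultiIndex.from_tuples(frames.columns)
    frames.index.name = "frame"
    return TrackingData(frames, fps=fps), stim


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrialSpec:
    """Parameters for a synthetic trial table."""

    arena_id: int | str = 4
    n_trials: int = 100
    true_p_right: float = 0.8
    naive_fraction: float = 0.15       # ~ 1 / trials-per-mouse
    t_max: float = 3600.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.true_p_right <= 1:
            raise ValidationError("true_p_right must be in [0, 1]")


def generate_trials(spec: SyntheticTrialSpec) -> pd.DataFrame:
    """I.i.d. Bernoulli arm choices over mice; first trial per mouse naive."""
    rng = np.random.default_rng(spec.seed)
    n_mice = max(1, int(round(spec.n_trials * spec.naive_fraction)))
    mouse_of = np.sort(rng.integers(0, n_mice, size=spec.n_trials))
    arena = ARENA_SPECS[spec.arena_id]
    t = np.sort(rng.uniform(0.0, spec.t_max, size=spec.n_trials))
    rows = []
    seen: set[int] = set()
    for i in range(spec.n_trials):
        m = int(mouse_of[i])
        naive = m not in seen
        seen.add(m)
        rows.append({
            "mouse_id": f"m{m:03d}",
            "arena_id": spec.arena_id,
            "naive": naive,
            "chosen_arm": "right" if rng.random() < spec.true_p_right else "left",
            "origin_arm": "right" if rng.random() < 0.5 else "left",
            "t_session": float(t[i]),
            "geodesic_ratio": arena.geodesic_ratio,
            "angle_ratio": arena.angle_ratio,
        })
    return pd.DataFrame(rows)


def generate_choice_glm_dataset(weights: dict[str, float],
                                arenas=(1, 2, 3, 4, 5),
                                n: int = 600, intercept: float = 0.0,
                                seed: int = 0
                                ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Trial table sampled from a known logistic choice model.

    ``weights`` maps predictor names (geodesic_ratio, angle_ratio,
    t_session, origin_arm) to coefficients on the normalized [0, 1] scale.
    Returns the table and the ground-truth weights (with intercept).
    """
    rng = np.random.default_rng(seed)
    specs = [ARENA_SPECS[a] for a in arenas]
    geo = np.array([s.geodesic_ratio for s in specs])
    ang = np.array([s.angle_ratio for s in specs])
    pick = rng.integers(0, len(specs), size=n)
    t = rng.uniform(0.0, 3600.0, size=n)
    origin = rng.random(n) < 0.5
    # normalize exactly as the fitting routine does
    def norm(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)
    X = {
        "geodesic_ratio": norm(geo[pick]),
        "angle_ratio": norm(ang[pick]),
        "t_session": norm(t),
        "origin_arm": origin.astype(float),
    }
    logit = intercept + sum(weights.get(k, 0.0) * X[k] for k in X)
    p = 1.0 / (1.0 + np.exp(-logit))
    right = rng.random(n) < p
    df = pd.DataFrame({
        "mouse_id": [f"m{i % 40:03d}" for i in range(n)],
        "arena_id": [specs[j].arena_id for j in pick],
        "naive": False,
        "chosen_arm": np.where(right, "right", "left"),
        "origin_arm": np.where(origin, "right", "left"),
        "t_session": t,
        "geodesic_ratio": geo[pick],
        "angle_ratio": ang[pick],
    })
    truth = {"const": intercept, **{k: weights.get(k, 0.0) for k in X}}
    return df, truth


def generate_heading_dataset(n_trials: int = 120, n_timepoints: int = 8,
                             max_separation_deg: float = 60.0,
                             noise_deg: float = 20.0, seed: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Headings whose left/right separation grows along the trajectory."""
    rng = np.random.default_rng(seed)
    arms = rng.integers(0, 2, size=n_trials)
    sep = np.linspace(0.0, max_separation_deg, n_timepoints)
    centers = np.where(arms[:, None] == 1, sep / 2, -sep / 2)
    H = centers + rng.normal(0.0, noise_deg, size=(n_trials, n_timepoints))
    return H, arms
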