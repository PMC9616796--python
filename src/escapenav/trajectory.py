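"""Pose-tracking post-processing and behavioral segmentation.

Ingests DeepLabCut-style tracking tables (frame x bodypart x {x, y,
likelihood}), applies the standard post-processing (median filtering,
removal of low-confidence samples, affine registration to the template
arena), derives grid-cell paths for guided agent training, heading
directions, shelter-threat trips and escape classifications.

Coordinates follow the grid convention after registration: ``x`` maps to the
lattice column and ``y`` to the row (row 0 at the top); one lattice cell
spans :data:`escapenav.config.CM_PER_CELL` centimeters.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .arena import Cell, GridWorld
from .config import (CM_PER_CELL, ESCAPE_DEFAULTS, TRACKING_DEFAULTS)
from .errors import (ContractViolationError, InvalidSessionError,
                     ValidationError)

BODYPARTS = ("snout", "neck", "body", "tail_base")


@dataclass
class TrackingData:
    """A tracking session: wide-format frame table plus acquisition rate.

    ``frames`` has a two-level column index (bodypart, coordinate) with
    coordinates ``x``, ``y``, ``likelihood`` per bodypart; the row index is
    the frame number (strictly increasing).
    """

    frames: pd.DataFrame
    fps: float = 30.0

    def __post_init__(self):
        idx = np.asarray(self.frames.index)
        if len(idx) > 1 and not (np.diff(idx) > 0).all():
            raise ValidationError("frame indices must be strictly increasing")

    @property
    def bodyparts(self) -> list[str]:
        return list(dict.fromkeys(self.frames.columns.get_level_values(0)))

    def xy(self, bodypart: str = "body") -> np.ndarray:
        return self.frames[bodypart][["x", "y"]].to_numpy(dtype=float)


@dataclass
class CellPath:
    """De-duplicated sequence of grid cells traversed in a session."""

    cells: list[Cell]
    session_id: str | None = None

    def __post_init__(self):
        for a, b in zip(self.cells, self.cells[1:]):
            if a == b:
                raise ValidationError("consecutive duplicate cells in CellPath")

    @property
    def n_state_changes(self) -> int:
        return len(self.cells) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, columns=["row", "col"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, session_id: str | None = None):
        return cls([(int(r), int(c)) for r, c in
                    zip(df["row"], df["col"])], session_id)


@dataclass(frozen=True)
class Trip:
    """One complete journey between the shelter and threat platforms."""

    direction: str                 # 'shelter_to_threat' | 'threat_to_shelter'
    start_frame: int               # last frame on the origin platform
    end_frame: int                 # first frame on the destination platform

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValidationError("trip end_frame must exceed start_frame")


# ---------------------------------------------------------------------------
# IO: DeepLabCut 3-row-header CSV and plain long format
# ---------------------------------------------------------------------------

def read_tracking(path: str | Path, fps: float = 30.0) -> TrackingData:
    """Read a tracking CSV, auto-detecting the dialect.

    Supported: DeepLabCut export (3 header rows: scorer / bodyparts /
    coords) and long format with columns frame, bodypart, x, y, likelihood.
    """
    path = Path(path)
    head = pd.read_csv(path, nrows=2, header=None)
    if str(head.iloc[0, 0]).strip().lower() == "scorer":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        df.columns = df.columns.droplevel(0)       # drop the scorer level
        df.index = df.index.astype(int)
        df.index.name = "frame"
        return TrackingData(df.astype(float), fps=fps)
    long = pd.read_csv(path)
    required = {"frame", "bodypart", "x", "y", "likelihood"}
    if not required.issubset(long.columns):
        raise ValidationError(
            f"unrecognized tracking dialect in {path}: need DeepLabCut "
            f"3-row header or long columns {sorted(required)}")
    wide = long.pivot(index="frame", columns="bodypart",
                      values=["x", "y", "likelihood"])
    wide = wide.swaplevel(axis=1).sort_index(axis=1)
    return TrackingData(wide.astype(float), fps=fps)


def write_tracking(data: TrackingData, path: str | Path,
                   scorer: str = "escapenav") -> None:
    """Write a DeepLabCut-style 3-row-header CSV."""
    df = data.frames.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"])
    df.to_csv(path, index_label="scorer")


# ---------------------------------------------------------------------------
# Affine registration
# ---------------------------------------------------------------------------

def estimate_affine(src_points: np.ndarray, dst_points: np.ndarray) -> np.ndarray:
    """Least-squares affine transform (2x3 matrix) from point correspondences.

    Three non-collinear correspondences (e.g. shelter, threat, arena center)
    determine the transform exactly; more are fitted in the least-squares
    sense.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape[0] < 3:
        raise ValidationError("affine estimation needs >= 3 correspondences")
    design = np.hstack([src, np.ones((len(src), 1))])
    coeffs, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return coeffs.T                               # (2, 3)


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return pts @ matrix[:, :2].T + matrix[:, 2]


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def preprocess_tracking(data: TrackingData,
                        likelihood_threshold: float = TRACKING_DEFAULTS["likelihood_threshold"],
                        median_window: int = TRACKING_DEFAULTS["median_window"],
                        affine: np.ndarray | None = None) -> TrackingData:
    """Standard tracking post-processing.

    Median filtering (window 7 frames) of each coordinate, masking of
    low-confidence samples (likelihood < 0.995) followed by linear
    interpolation, and optional affine registration to the template arena.
    A bodypart with no confident frame at all cannot be recovered and raises.
    """
    if len(data.frames) < median_window:
        raise ValidationError(
            f"need at least {median_window} frames, got {len(data.frames)}")
    frames = data.frames.copy()
    for bp in data.bodyparts:
        lik = frames[(bp, "likelihood")].to_numpy(dtype=float)
        if (lik < likelihood_threshold).all():
            raise InvalidSessionError(
                f"bodypart {bp!r} has no frame above the likelihood "
                f"threshold {likelihood_threshold}")
        for coord in ("x", "y"):
            col = frames[(bp, coord)].to_numpy(dtype=float)
            col = median_filter(col, size=median_window, mode="nearest")
            col[lik < likelihood_threshold] = np.nan
            ser = pd.Series(col).interpolate(limit_direction="both")
            frames[(bp, coord)] = ser.to_numpy()
    if affine is not None:
        for bp in data.bodyparts:
            xy = frames[bp][["x", "y"]].to_numpy(dtype=float)
            xy = apply_affine(affine, xy)
            frames[(bp, "x")] = xy[:, 0]
            frames[(bp, "y")] = xy[:, 1]
    return TrackingData(frames, fps=data.fps)


# ---------------------------------------------------------------------------
# Cell assignment
# ---------------------------------------------------------------------------

def assign_cells(data: TrackingData, world: GridWorld,
                 bodypart: str = "body",
                 snap_radius: float = TRACKING_DEFAULTS["snap_radius_cells"],
                 session_id: str | None = None) -> CellPath:
    """Map registered frames to nearest accessible cells and collapse dwell.

    Each frame's ``bodypart`` position (grid coordinates: x = column,
    y = row) is snapped to the nearest accessible cell center (Euclidean;
    exact ties resolved toward the lexicographically smaller (row, col)).
    Consecutive duplicates are collapsed so only state changes remain. A
    frame farther than ``snap_radius`` cells from every accessible cell
    invalidates the session, mirroring the discarding of unregistrable
    experimental sessions.
    """
    from scipy.spatial import cKDTree
    cells = np.array(world.accessible_cells())    # lexicographically sorted
    tree = cKDTree(cells)
    xy = data.xy(bodypart)
    pts = np.column_stack([xy[:, 1], xy[:, 0]])   # (row, col)
    if np.isnan(pts).any():
        raise InvalidSessionError("NaN positions remain after preprocessing")
    dist, idx = tree.query(pts)
    if (dist > snap_radius).any():
        bad = int(np.argmax(dist > snap_radius))
        raise InvalidSessionError(
            f"frame {data.frames.index[bad]} lies {dist[bad]:.2f} cells from "
            f"the nearest accessible cell (snap radius {snap_radius})")
    # resolve near-exact ties toward the lexicographically smaller cell
    ties = tree.query_ball_point(pts, r=dist + 1e-9)
    seq: list[Cell] = []
    for frame_i, cand in enumerate(ties):
        best = min(cand, key=lambda j: (cells[j][0], cells[j][1])) \
            if len(cand) > 1 else cand[0] if cand else int(idx[frame_i])
        cell = (int(cells[best][0]), int(cells[best][1]))
        if not seq or seq[-1] != cell:
            seq.append(cell)
    return CellPath(seq, session_id=session_id)


# ---------------------------------------------------------------------------
# Heading direction
# ---------------------------------------------------------------------------

def heading_direction(frame: pd.Series | dict,
                      shelter_direction: tuple[float, float] = (0.0, -1.0)
                      ) -> float:
    """Allocentric heading of one frame, in degrees, shelter direction at 0.

    The tail_base->body and body->snout vectors are normalized and averaged;
    the returned angle is the signed angle between that mean heading and
    ``shelter_direction`` (default: decreasing y, i.e. toward the top of the
    template), positive counterclockwise in the x/y plane, range (-180, 180].
    Returns NaN when either segment has zero length.
    """
    def _vec(a, b):
        return np.array([frame[(b, "x")] - frame[(a, "x")],
                         frame[(b, "y")] - frame[(a, "y")]], dtype=float)

    v1 = _vec("tail_base", "body")
    v2 = _vec("body", "snout")
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return float("nan")
    mean = v1 / n1 + v2 / n2
    if np.hypot(*mean) < 1e-12:
        return float("nan")
    ref = np.asarray(shelter_direction, dtype=float)
    # y grows downward in image/grid coordinates; use the standard
    # right-handed angle in (x, -y)
    ang = (np.arctan2(-mean[1], mean[0]) - np.arctan2(-ref[1], ref[0]))
    deg = np.degrees(ang)
    deg = (deg + 180.0) % 360.0 - 180.0
    return float(180.0 if np.isclose(deg, -180.0) else deg)


def headings(data: TrackingData, **kwargs) -> pd.Series:
    """Per-frame heading angles for a session."""
    vals = [heading_direction(row, **kwargs)
            for _, row in data.frames.iterrows()]
    return pd.Series(vals, index=data.frames.index, name="heading_deg")


# ---------------------------------------------------------------------------
# Region assignment and trips
# ---------------------------------------------------------------------------

def region_sequence(data: TrackingData, world: GridWorld,
                    bodypart: str = "body") -> pd.Series:
    """Region name per frame ('' where the position is in no region)."""
    xy = data.xy(bodypart)
    rows = np.clip(np.round(xy[:, 1]).astype(int), 0, world.shape[0] - 1)
    cols = np.clip(np.round(xy[:, 0]).astype(int), 0, world.shape[1] - 1)
    out = np.full(len(rows), "", dtype=object)
    for name, mask in world.regions.items():
        hit = mask[rows, cols]
        out[hit] = name
    return pd.Series(out, index=data.frames.index, name="region")


def segment_trips(data: TrackingData, roi_masks: dict[str, np.ndarray] | GridWorld,
                  bodypart: str = "body") -> list[Trip]:
    """Extract complete shelter<->threat trips from a session.

    A trip starts at the last frame on the origin platform and ends on
    arrival at the other platform; excursions that return to the origin
    platform without reaching the other one are discarded.
    """
    if isinstance(roi_masks, GridWorld):
        world = roi_masks
    else:
        world = GridWorld.__new__(GridWorld)     # light wrapper for regions
        occupancy = np.zeros(next(iter(roi_masks.values())).shape, dtype=bool)
        for m in roi_masks.values():
            occupancy |= m
        world.occupancy = occupancy
        world.regions = dict(roi_masks)
    regions = region_sequence(data, world, bodypart=bodypart)
    platforms = {"shelter", "threat"}
    trips: list[Trip] = []
    origin: str | None = None
    last_on_origin: int | None = None
    for frame, reg in regions.items():
        if reg not in platforms:
            continue
        if origin is None or reg == origin:
            origin, last_on_origin = reg, frame
        else:                                     # arrived at the other one
            direction = ("shelter_to_threat" if origin == "shelter"
                         else "threat_to_shelter")
            trips.append(Trip(direction, int(last_on_origin), int(frame)))
            origin, last_on_origin = reg, frame
    return trips


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.direction, t.start_frame, t.end_frame) for t in trips],
        columns=["direction", "start_frame", "end_frame"])


# ---------------------------------------------------------------------------
# Escape classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EscapeClassification:
    is_escape: bool
    chosen_arm: str                # 'left' | 'right' | 'center' | 'none'
    time_to_leave: float           # s from stimulus to leaving threat platform
    exit_speed: float              # cm/s when leaving the platform
    qualifies_for_arm_analysis: bool
    usable: bool = True


def speed_profile(data: TrackingData, bodypart: str = "body",
                  smoothing: int = TRACKING_DEFAULTS["speed_smoothing_frames"],
                  cm_per_unit: float = CM_PER_CELL) -> np.ndarray:
    """Instantaneous speed (cm/s) via central differences of position,
    smoothed with a short moving average (default 5 frames)."""
    xy = data.xy(bodypart) * cm_per_unit
    if len(xy) < 3:
        raise ValidationError("need >= 3 frames for a speed estimate")
    vel = np.gradient(xy, axis=0) * data.fps
    speed = np.hypot(vel[:, 0], vel[:, 1])
    kernel = np.ones(smoothing) / smoothing
    return np.convolve(speed, kernel, mode="same")


def classify_escape(data: TrackingData, stimulus_frame: int,
                    world: GridWorld,
                    fps: float | None = None,
                    escape_window_s: float = ESCAPE_DEFAULTS["escape_window_s"],
                    arm_window_s: float = ESCAPE_DEFAULTS["arm_choice_window_s"],
                    speed_threshold: float = ESCAPE_DEFAULTS["speed_threshold_cm_s"],
                    cm_per_unit: float = CM_PER_CELL,
                    bodypart: str = "body") -> EscapeClassification:
    """Classify one post-stimulus trial.

    A trial is an escape iff the shelter platform is reached within 10 s of
    stimulus onset. The chosen arm is the first arm region entered after
    leaving the threat platform. For arm-choice and dead-end analyses the
    stricter criteria apply: the platform must be left within 4 s and at a
    speed above 35 cm/s.
    """
    fps = fps or data.fps
    horizon = stimulus_frame + int(round(escape_window_s * fps))
    idx = data.frames.index
    if stimulus_frame not in idx:
        raise ContractViolationError(
            f"stimulus frame {stimulus_frame} not in session")
    window = data.frames.loc[stimulus_frame:horizon]
    if len(window) < int(round(escape_window_s * fps)):
        return EscapeClassification(False, "none", float("nan"), float("nan"),
                                    False, usable=False)
    sub = TrackingData(window, fps=fps)
    if np.isnan(sub.xy(bodypart)).any():
        return EscapeClassification(False, "none", float("nan"), float("nan"),
                                    False, usable=False)
    regions = region_sequence(sub, world, bodypart=bodypart)
    arrive = regions[regions == "shelter"]
    is_escape = len(arrive) > 0
    off = regions[(regions != "threat")]
    if off.empty:
        return EscapeClassification(False, "none", float("nan"), float("nan"),
                                    False)
    leave_frame = int(off.index[0])
    time_to_leave = (leave_frame - stimulus_frame) / fps
    arm_names = {"left_arm": "left", "right_arm": "right",
                 "center_arm": "center"}
    chosen = "none"
    for reg in regions.loc[leave_frame:]:
        if reg in arm_names:
            chosen = arm_names[reg]
            break
    speeds = speed_profile(sub, bodypart=bodypart, cm_per_unit=cm_per_unit)
    exit_speed = float(speeds[sub.frames.index.get_loc(leave_frame)])
    qualifies = (is_escape and time_to_leave <= arm_window_s
                 and exit_speed > speed_threshold)
    return EscapeClassification(bool(is_escape), chosen, float(time_to_leave),
                                exit_speed, bool(qualifies))
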