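"""Trajectory linking and migration metrics.

Links per-frame centroid clouds into identity-preserving tracks with a
deterministic greedy mutual-nearest-neighbour rule, then computes the
standard time-lapse readouts: trajectory (path) distance, average velocity,
and neighbouring-pair distance ratios relative to the initial distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .synthsheet import TRACK_CSV_COLUMNS, CentroidFrame

logger = logging.getLogger(__name__)

#: Default evaluation time (min) for neighbouring-pair distance ratios.
DEFAULT_PAIR_EVAL_MIN = 400.0


@dataclass
class TrackSet:
    """Identity-linked trajectories.

    ``df`` holds one row per (cell, frame) with columns
    frame, time_min, cell_id, x_um, y_um; within a track the frame indices
    strictly increase and no two tracks share a (frame, point).
    """

    df: pd.DataFrame
    max_disp: float = np.inf

    def cell_ids(self) -> list[int]:
        return sorted(self.df["cell_id"].unique())

    def track(self, cell_id: int) -> pd.DataFrame:
        sub = self.df[self.df["cell_id"] == cell_id].sort_values("frame")
        if sub.empty:
            raise KeyError(f"unknown cell_id {cell_id}")
        return sub

    def points(self, cell_id: int) -> np.ndarray:
        return self.track(cell_id)[["x_um", "y_um"]].to_numpy()

    def to_csv(self, path) -> None:
        self.df[TRACK_CSV_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, max_disp: float = np.inf) -> "TrackSet":
        return cls(df=pd.read_csv(path), max_disp=max_disp)


@dataclass
class PairSeries:
    """Distance history of one neighbouring cell pair."""

    pair_id: int
    a: int
    b: int
    times: np.ndarray  # min, frames where both members exist
    distances: np.ndarray  # µm
    ratio_at_t: float  # distance(t_eval) / distance(t0)
    t_eval: float


def _mutual_nn(pts_a: np.ndarray, pts_b: np.ndarray, max_dist: float):
    """Mutual nearest-neighbour matches within max_dist.

    Returns (i, j) index pairs.  np.argmin resolves ties toward the lower
    index, which fixes the documented deterministic tie-break.
    """
    if len(pts_a) == 0 or len(pts_b) == 0:
        return []
    d = cdist(pts_a, pts_b)
    fwd = d.argmin(axis=1)  # a -> nearest b
    bwd = d.argmin(axis=0)  # b -> nearest a
    matches = []
    for i in range(len(pts_a)):
        j = fwd[i]
        if bwd[j] == i and d[i, j] <= max_dist:
            matches.append((i, int(j)))
    return matches


def link_tracks(frames: list[CentroidFrame], max_disp: float) -> TrackSet:
    """Greedy mutual-nearest-neighbour linking across consecutive frames.

    Points in frame t+1 are matched to points in frame t when each is the
    other's nearest neighbour and the displacement is at most ``max_disp``
    µm; unmatched points terminate their track or start a new one.  The
    assignment is deterministic (argmin ties resolve to the lowest index).
    """
    if not frames:
        raise ValueError("need at least one frame to link")
    if len(frames) < 2:
        raise ValueError("need at least two frames to link")

    rows = []
    next_id = 0
    # ids of the points in the previous frame, aligned with its point order
    prev_ids = []
    for i in range(len(frames[0])):
        prev_ids.append(next_id)
        next_id += 1
    for i, pid in enumerate(prev_ids):
        x, y = frames[0].points[i]
        rows.append((frames[0].frame_index, frames[0].time_min, pid, x, y))

    for prev, cur in zip(frames, frames[1:]):
        matches = dict()  # cur index -> track id
        for i, j in _mutual_nn(prev.points, cur.points, max_disp):
            matches[j] = prev_ids[i]
        cur_ids = []
        for j in range(len(cur)):
            if j in matches:
                cur_ids.append(matches[j])
            else:
                cur_ids.append(next_id)
                next_id += 1
        for j, pid in enumerate(cur_ids):
            x, y = cur.points[j]
            rows.append((cur.frame_index, cur.time_min, pid, x, y))
        prev_ids = cur_ids

    df = pd.DataFrame(rows, columns=TRACK_CSV_COLUMNS)
    return TrackSet(df=df, max_disp=max_disp)


def trajectory_distance(points: np.ndarray) -> float:
    """Total path length (µm): sum of Euclidean step lengths.

    A single-point track has zero trajectory distance.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 1:
        raise ValueError("track must contain at least one point")
    if len(points) == 1:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def average_velocity(points: np.ndarray, frame_interval: float) -> float:
    """Average migration speed: trajectory distance over elapsed capture time.

    ``points`` must span at least two frames; the elapsed time is
    (n_steps * frame_interval) minutes.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        raise ValueError("velocity undefined for a track spanning < 2 frames")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    n_steps = len(points) - 1
    return trajectory_distance(points) / (n_steps * frame_interval)


def select_neighbor_pairs(
    frame0: CentroidFrame,
    max_pair_dist: float,
    n_pairs: int = 15,
) -> list[tuple[int, int]]:
    """Adjacent-cell pairs at frame 0: mutual nearest neighbours.

    Pairs farther apart than ``max_pair_dist`` are excluded; survivors are
    sorted by distance (closest first) and truncated to ``n_pairs``.  Returns
    an empty list, with a warning, when nothing qualifies.
    """
    if len(frame0) < 2:
        raise ValueError("need at least two points to form pairs")
    d = cdist(frame0.points, frame0.points)
    np.fill_diagonal(d, np.inf)
    nn_dist = d.min(axis=1)
    # mutual-NN candidates, counting equidistant neighbours as ties so that
    # symmetric configurations (e.g. a square) pair off completely
    tol = 1e-9
    candidates = []
    for i in range(len(d)):
        for j in range(i + 1, len(d)):
            if (
                d[i, j] <= max_pair_dist
                and d[i, j] <= nn_dist[i] * (1 + tol)
                and d[i, j] <= nn_dist[j] * (1 + tol)
            ):
                candidates.append((d[i, j], i, j))
    if not candidates:
        warnings.warn("no mutual nearest-neighbour pair within max_pair_dist")
        return []
    candidates.sort()
    used: set[int] = set()
    pairs = []
    for _, i, j in candidates:  # greedy disjoint matching, closest first
        if i in used or j in used:
            continue
        pairs.append((i, j))
        used.update((i, j))
        if len(pairs) == n_pairs:
            break
    return pairs


def _nearest_frame(times: np.ndarray, t_eval: float) -> int:
    """Index of the frame time closest to t_eval; ties go to the earlier frame."""
    diffs = np.abs(times - t_eval)
    return int(diffs.argmin())  # argmin ties -> lower index -> earlier frame


def pair_distance_ratio(
    tracks: TrackSet,
    pairs: list[tuple[int, int]],
    t_eval: float = DEFAULT_PAIR_EVAL_MIN,
) -> list[PairSeries]:
    """Neighbouring-cell distance at t_eval as a ratio to the initial distance.

    For each pair the Euclidean distance is measured at the frame whose time
    is nearest ``t_eval`` (ties toward the earlier frame) and divided by the
    frame-0 distance.  Pairs with a member missing at either time point are
    skipped with a warning; a zero initial distance is an error.
    """
    out = []
    for pid, (a, b) in enumerate(pairs):
        ta, tb = tracks.track(a), tracks.track(b)
        merged = ta.merge(tb, on=["frame", "time_min"], suffixes=("_a", "_b"))
        if merged.empty:
            warnings.warn(f"pair ({a}, {b}) shares no frames; skipped")
            continue
        times = merged["time_min"].to_numpy()
        dist = np.hypot(
            merged["x_um_a"] - merged["x_um_b"],
            merged["y_um_a"] - merged["y_um_b"],
        ).to_numpy()
        k_eval = _nearest_frame(times, t_eval)
        # a member that left the field before t_eval leaves the nearest
        # shared frame more than one frame interval short of t_eval
        spacing = np.diff(np.sort(times)).max() if len(times) > 1 else 0.0
        if abs(times[k_eval] - t_eval) > spacing + 1e-9:
            warnings.warn(f"pair ({a}, {b}) not observed near t={t_eval}; skipped")
            continue
        d0 = dist[times.argmin()]
        if d0 <= 0:
            raise ValueError(f"pair ({a}, {b}) has zero initial distance")
        out.append(
            PairSeries(
                pair_id=pid, a=a, b=b, times=times, distances=dist,
                ratio_at_t=float(dist[k_eval] / d0), t_eval=float(times[k_eval]),
            )
        )
        logger.debug("pair %d (%d,%d): d0=%.3f d(t)=%.3f ratio=%.3f",
                     pid, a, b, d0, dist[k_eval], dist[k_eval] / d0)
    return out


def pair_report(series: list[PairSeries]) -> pd.DataFrame:
    """Tabulate pair ratios (pair_id, a, b, d0_um, d_t_um, ratio)."""
    rows = [
        (s.pair_id, s.a, s.b, s.distances[s.times.argmin()],
         s.distances[_nearest_frame(s.times, s.t_eval)], s.ratio_at_t)
        for s in series
    ]
    return pd.DataFrame(rows, columns=["pair_id", "a", "b", "d0_um", "d_t_um", "ratio"])
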