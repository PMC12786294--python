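"""Frame-to-frame linking of detected puncta into trajectories.

Linking follows a simple linear-assignment (LAP) scheme: within each frame
transition the assignment between open tracks and new detections minimizes
total squared displacement among candidate pairs closer than a fixed
distance gate. Tracks missing detections may bridge gaps up to a maximum
number of frames (with the same, un-widened gate); longer gaps terminate
the track and later detections start new ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import Spot

__all__ = ["Trajectory", "link_spots", "trajectory_length", "trajectory_range", "trajectories_to_table", "trajectories_from_table"]


@dataclass
class Trajectory:
    """A time-linked sequence of punctum positions.

    ``frames`` are strictly increasing; ``gap_flags`` marks samples that
    reconnected after one or more missed frames. Positions are in µm.
    """

    track_id: int
    frames: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    x_um: list[float] = field(default_factory=list)
    y_um: list[float] = field(default_factory=list)
    gap_flags: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    def append(self, frame: int, t: float, x: float, y: float, gap: bool = False) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.times.append(t)
        self.x_um.append(x)
        self.y_um.append(y)
        self.gap_flags.append(gap)


def link_spots(
    spots_by_frame: list[list[Spot]],
    max_disp_px: float = 5.0,
    max_gap_frames: int = 5,
    pixel_size: float = 0.1,
    frame_interval: float = 0.2,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Parameters
    ----------
    spots_by_frame : list of per-frame spot lists (may be empty per frame).
    max_disp_px : distance gate in pixels; candidate links farther than
        this (per linking step, constant during gaps) are forbidden.
    max_gap_frames : a track absent for more than this many consecutive
        frames is terminated and treated as a new particle thereafter.

    The per-step assignment is an optimal bipartite matching on squared
    distance (Jonker–Volgenant via :func:`scipy.optimize.linear_sum_assignment`)
    with birth/death alternatives at the gate cost, which makes linking
    independent of spot order except for exact-distance ties (then resolved
    by input order).
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be positive")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be non-negative")
    gate_um = max_disp_px * pixel_size
    gate2 = gate_um * gate_um

    trajectories: list[Trajectory] = []
    # active tracks: (traj, last_frame, last_xy)
    active: list[Trajectory] = []
    next_id = 0

    for frame_idx, spots in enumerate(spots_by_frame):
        t = frame_idx * frame_interval
        coords = np.array([[s.x_um, s.y_um] for s in spots]).reshape(-1, 2)
        n_spots = len(spots)

        # drop tracks whose gap exceeded the maximum
        still_active = []
        for traj in active:
            if frame_idx - traj.frames[-1] - 1 > max_gap_frames:
                trajectories.append(traj)
            else:
                still_active.append(traj)
        active = still_active
        n_tracks = len(active)

        assigned_spot = [False] * n_spots
        if n_tracks and n_spots:
            last = np.array([[tr.x_um[-1], tr.y_um[-1]] for tr in active])
            d2 = ((last[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
            # augmented square matrix: top-left = link costs (inf outside the
            # gate), diagonal blocks = birth/death alternatives at gate cost
            big = 1e12
            n = n_tracks + n_spots
            cost = np.full((n, n), 0.0)
            link = np.where(d2 <= gate2, d2, big)
            cost[:n_tracks, :n_spots] = link
            cost[:n_tracks, n_spots:] = big
            cost[n_tracks:, :n_spots] = big
            np.fill_diagonal(cost[:n_tracks, n_spots:], gate2)
            np.fill_diagonal(cost[n_tracks:, :n_spots], gate2)
            # lower-right: transposed link costs keep the matrix feasible
            cost[n_tracks:, n_spots:] = link.T
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if r < n_tracks and c < n_spots and d2[r, c] <= gate2:
                    traj = active[r]
                    gap = frame_idx - traj.frames[-1] > 1
                    traj.append(frame_idx, t, coords[c, 0], coords[c, 1], gap=gap)
                    assigned_spot[c] = True

        for c in range(n_spots):
            if not assigned_spot[c]:
                traj = Trajectory(track_id=next_id)
                next_id += 1
                traj.append(frame_idx, t, coords[c, 0], coords[c, 1])
                active.append(traj)

    trajectories.extend(active)
    trajectories.sort(key=lambda tr: tr.track_id)
    return trajectories


def trajectory_length(traj: Trajectory) -> float:
    """Total path length in µm: sum of Euclidean steps between consecutive
    samples (a bridged gap contributes one straight step)."""
    if len(traj) < 2:
        raise ValueError("trajectory_length requires at least 2 samples")
    pos = traj.positions()
    return float(np.sqrt(((np.diff(pos, axis=0)) ** 2).sum(axis=1)).sum())


def trajectory_range(traj: Trajectory) -> float:
    """Spatial range in µm: maximum pairwise distance between samples."""
    if len(traj) < 2:
        raise ValueError("trajectory_range requires at least 2 samples")
    pos = traj.positions()
    # convex-hull-free O(n^2) is fine at trajectory sizes (tens of samples)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def trajectories_to_table(trajs: list[Trajectory], pixel_size: float) -> pd.DataFrame:
    rows = []
    for tr in trajs:
        for f, t, x, y, g in zip(tr.frames, tr.times, tr.x_um, tr.y_um, tr.gap_flags):
            rows.append((tr.track_id, f, t, x, y, x / pixel_size, y / pixel_size, int(g)))
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "t_s", "x_um", "y_um", "x_px", "y_px", "gap_flag"],
    )


def trajectories_from_table(df: pd.DataFrame) -> list[Trajectory]:
    trajs = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tr = Trajectory(track_id=int(tid))
        for _, row in grp.iterrows():
            tr.append(
                int(row["frame"]),
                float(row["t_s"]),
                float(row["x_um"]),
                float(row["y_um"]),
                gap=bool(row.get("gap_flag", 0)),
            )
        trajs.append(tr)
    return trajs
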