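"""Shared fixtures: trajectory builders and small synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from punctakit.synthetic import GroundTruth, SimulationConfig, simulate_trajectories
from punctakit.tracking import Trajectory


def trajectories_from_ground_truth(gt: GroundTruth) -> list[Trajectory]:
    """Convert a generator's true positions into Trajectory objects."""
    trajs = []
    for sid, grp in gt.positions.groupby("spot_id", sort=True):
        tr = Trajectory(track_id=int(sid))
        for _, r in grp.sort_values("frame").iterrows():
            tr.append(int(r["frame"]), float(r["t_s"]), float(r["x_um"]), float(r["y_um"]))
        trajs.append(tr)
    return trajs


def simulate_track_ensemble(motion, n_tracks: int, seed: int, n_frames: int = 50) -> list[Trajectory]:
    """Simulate n_tracks independent trajectories of one motion mode."""
    from punctakit.synthetic import SpotSpec

    spots = [SpotSpec(initial_position=(5.0, 5.0), motion=motion) for _ in range(n_tracks)]
    cfg = SimulationConfig(spots=spots, n_frames=n_frames, seed=seed)
    return trajectories_from_ground_truth(simulate_trajectories(cfg))


def make_trajectory(points, dt: float = 0.2, track_id: int = 0) -> Trajectory:
    """Trajectory from a list of (x_um, y_um) at consecutive frames."""
    tr = Trajectory(track_id=track_id)
    for f, (x, y) in enumerate(points):
        tr.append(f, f * dt, float(x), float(y))
    return tr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
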