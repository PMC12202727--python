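"""Linking of spot coordinates across timeframes into trajectories.

A deliberately simple, deterministic nearest-neighbour linker in the spirit
of classical particle-tracking codes: for each consecutive frame pair, the
candidate links shorter than ``max_disp`` are sorted by distance and matched
greedily with mutual exclusion, so a spot joins at most one trajectory and
two spots never swap identities through an implausibly long link.  Adequate
for the sparse, slowly moving spots of time-lapse MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "link", "trajectory_velocity", "filter_trajectories", "trajectories_table"]


@dataclass
class Trajectory:
    """One linked spot across one or more frames (coordinates in mm)."""

    traj_id: int
    frames: list = field(default_factory=list)
    positions: list = field(default_factory=list)

    def add(self, frame: int, position) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(int(frame))
        self.positions.append(np.asarray(position, dtype=float))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def displacement(self) -> float:
        """Net start-to-end displacement in mm."""
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def path_length(self) -> float:
        return float(
            sum(
                np.linalg.norm(b - a)
                for a, b in zip(self.positions[:-1], self.positions[1:])
            )
        )


def link(spots_per_frame: list, max_disp: float) -> list:
    """Link per-frame spot coordinate lists into trajectories.

    ``spots_per_frame``: time-ordered list; each entry is an (n_i, d) array
    of coordinates (mm).  Links longer than ``max_disp`` are forbidden;
    candidate links are matched globally shortest first (ties broken by spot
    indices, making the result invariant to input order up to relabeling).
    Unmatched spots start new trajectories; no gap closing.
    """
    trajectories: list[Trajectory] = []
    active: dict[int, Trajectory] = {}  # spot index in previous frame -> traj
    next_id = 0
    prev = None
    for f, spots in enumerate(spots_per_frame):
        spots = np.asarray(spots, dtype=float)
        if spots.size == 0:
            spots = np.zeros((0, prev.shape[1] if prev is not None else 1))
        else:
            spots = spots.reshape(spots.shape[0], -1)
        assigned: dict[int, Trajectory] = {}
        if prev is not None and len(prev) and len(spots):
            d = np.linalg.norm(prev[:, None, :] - spots[None, :, :], axis=2)
            cand = [
                (d[i, j], i, j)
                for i in range(len(prev))
                for j in range(len(spots))
                if d[i, j] <= max_disp
            ]
            cand.sort()
            used_prev: set[int] = set()
            used_new: set[int] = set()
            for dist, i, j in cand:
                if i in used_prev or j in used_new or i not in active:
                    continue
                used_prev.add(i)
                used_new.add(j)
                traj = active[i]
                traj.add(f, spots[j])
                assigned[j] = traj
        for j in range(len(spots)):
            if j not in assigned:
                traj = Trajectory(next_id)
                next_id += 1
                traj.add(f, spots[j])
                trajectories.append(traj)
                assigned[j] = traj
        active = assigned
        prev = spots
    return trajectories


def trajectory_velocity(traj: Trajectory, frame_duration_s: float) -> float:
    """Mean speed in mm/min: total inter-frame path length / elapsed time.

    Frames need not be consecutive in principle, but the linker never skips
    frames, so elapsed time is (n_frames - 1) * frame_duration.
    """
    if len(traj) < 2:
        raise ValueError("velocity needs at least 2 frames")
    elapsed_min = (traj.frames[-1] - traj.frames[0]) * frame_duration_s / 60.0
    return traj.path_length() / elapsed_min


def filter_trajectories(
    trajectories: list,
    n_frames_total: int,
    min_frames: int = 2,
    exclude_stationary: bool = True,
    stationary_tol_mm: float = 0.0,
) -> list:
    """Drop short tracks and, optionally, stationary features.

    Stationary features present in every frame (small vessels mimicking
    cells) are excluded when their net displacement does not exceed
    ``stationary_tol_mm``.
    """
    out = []
    for t in trajectories:
        if len(t) < min_frames:
            continue
        if (
            exclude_stationary
            and len(t) == n_frames_total
            and t.displacement <= stationary_tol_mm
        ):
            continue
        out.append(t)
    return out


def trajectories_table(trajectories: list, frame_duration_s: float) -> pd.DataFrame:
    """Long-format table (traj_id, frame, x, y[, z], v_mm_per_min)."""
    rows = []
    for t in trajectories:
        v = trajectory_velocity(t, frame_duration_s) if len(t) >= 2 else np.nan
        for f, pos in zip(t.frames, t.positions):
            row = {"traj_id": t.traj_id, "frame": f}
            for ax, name in zip(range(len(pos)), "xyz"):
                row[name] = pos[ax]
            row["v_mm_per_min"] = v
            rows.append(row)
    return pd.DataFrame(rows)
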