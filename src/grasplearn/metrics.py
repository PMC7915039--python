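"""Kinematic performance metrics for the grasp-move-place task.

Three per-trial metrics are computed from the object-centre trajectory
after resampling to a uniform 100 Hz grid:

* completion time — total time the object is moving (speed above a
  gate threshold; the gate of 0 is the literal "velocity non-zero"
  rule, appropriate for noise-free data);
* pathlength — accumulated 3-D displacement across consecutive moving
  samples;
* placement error — in-plane distance between the object's final
  resting centre projected onto the table surface and the target
  centre.

Speed is estimated by central differences (one-sided at the ends), and
the final resting pose is the mean position over the trailing
non-moving segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synth import ObjectTrajectory

__all__ = [
    "TrialMetrics",
    "resample_trajectory",
    "compute_speed",
    "moving_mask",
    "completion_time",
    "pathlength",
    "placement_error",
    "score_trial",
    "METRIC_RATE",
    "DEFAULT_V_GATE",
]

METRIC_RATE = 100.0     # Hz, analysis grid
DEFAULT_V_GATE = 0.01   # m/s, speed gate for measured (noisy) data


@dataclass
class TrialMetrics:
    """Per-trial metric triple with gating diagnostics."""

    completion_time: float   # s
    pathlength: float        # m
    placement_error: float   # m
    n_moving: int
    v_gate: float

    def as_dict(self) -> dict[str, float]:
        return {"completion_time": self.completion_time,
                "pathlength": self.pathlength,
                "placement_error": self.placement_error}


def resample_trajectory(traj: ObjectTrajectory,
                        rate: float = METRIC_RATE) -> ObjectTrajectory:
    """Linear interpolation onto a uniform grid spanning the time range."""
    t = np.asarray(traj.timestamps, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt = 1.0 / rate
    n = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    grid = t[0] + np.arange(n) * dt
    pos = np.column_stack([
        np.interp(grid, t, traj.positions[:, k]) for k in range(3)])
    return replace(traj, timestamps=grid, positions=pos)


def compute_speed(traj: ObjectTrajectory) -> np.ndarray:
    """Central-difference speed (m/s) at each sample of a uniform grid."""
    t = traj.timestamps
    vel = np.gradient(traj.positions, t, axis=0)
    return np.linalg.norm(vel, axis=1)


_NUMERICAL_SPEED_FLOOR = 1e-9  # m/s; below this, "motion" is round-off


def moving_mask(speed: np.ndarray, v_gate: float) -> np.ndarray:
    """True where the object is moving (speed strictly above the gate).

    With ``v_gate=0`` this is the literal velocity-non-zero rule, except
    that speeds below 1e-9 m/s are treated as rest: linear interpolation
    of a perfectly stationary segment can leave last-ulp position
    differences that would otherwise register as motion.
    """
    if v_gate < 0:
        raise ValueError("v_gate must be >= 0")
    return np.asarray(speed) > max(v_gate, _NUMERICAL_SPEED_FLOOR)


def completion_time(traj: ObjectTrajectory,
                    v_gate: float = DEFAULT_V_GATE) -> float:
    """Moving time: (number of moving samples) x sample period."""
    t = traj.timestamps
    dt = float(t[1] - t[0])
    mask = moving_mask(compute_speed(traj), v_gate)
    return float(mask.sum() * dt)


def pathlength(traj: ObjectTrajectory,
               v_gate: float = DEFAULT_V_GATE) -> float:
    """Accumulated displacement across consecutive moving samples."""
    mask = moving_mask(compute_speed(traj), v_gate)
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    both_moving = mask[:-1] & mask[1:]
    return float(steps[both_moving].sum())


def _project(p: np.ndarray, plane_point: np.ndarray,
             normal: np.ndarray) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    return p - np.dot(p - plane_point, n) * n


def placement_error(
    traj: ObjectTrajectory,
    target_center: np.ndarray | None = None,
    table_plane: tuple[np.ndarray, np.ndarray] | None = None,
    v_gate: float = DEFAULT_V_GATE,
) -> float:
    """In-plane distance from the final resting centre to the target.

    The final pose is the mean position over the trailing non-moving
    segment; a trajectory still moving at its last sample is rejected.
    Both the final pose and the target centre are orthogonally projected
    onto the table plane before measuring the distance.
    """
    target = (np.asarray(target_center, dtype=float)
              if target_center is not None else traj.target_center)
    if table_plane is not None:
        plane_point, normal = (np.asarray(v, dtype=float)
                               for v in table_plane)
    else:
        plane_point, normal = traj.table_point, traj.table_normal
    mask = moving_mask(compute_speed(traj), v_gate)
    if mask[-1]:
        raise ValueError("no trailing rest segment: object still moving "
                         "at the final sample")
    last_moving = np.nonzero(mask)[0]
    start = int(last_moving[-1]) + 1 if len(last_moving) else 0
    final = traj.positions[start:].mean(axis=0)
    d = _project(final, plane_point, normal) - _project(target, plane_point,
                                                        normal)
    return float(np.linalg.norm(d))


def score_trial(
    traj: ObjectTrajectory,
    v_gate: float = DEFAULT_V_GATE,
    rate: float = METRIC_RATE,
) -> TrialMetrics:
    """Resample, gate on speed and compute the three metrics."""
    rs = resample_trajectory(traj, rate)
    speed = compute_speed(rs)
    mask = moving_mask(speed, v_gate)
    dt = 1.0 / rate
    steps = np.linalg.norm(np.diff(rs.positions, axis=0), axis=1)
    return TrialMetrics(
        completion_time=float(mask.sum() * dt),
        pathlength=float(steps[mask[:-1] & mask[1:]].sum()),
        placement_error=placement_error(rs, v_gate=v_gate),
        n_moving=int(mask.sum()),
        v_gate=v_gate)
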