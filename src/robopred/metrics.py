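"""Behavioral metrics from trial trajectories.

Nine dependent measures are computed on the observation window of a trial,
split into three 2-min time bins: avoidance (distance to the replica, time
in the opposite vertical half), geotaxis (mean height, time in the bottom
third, entries into the bottom section), activity (speed, acceleration
magnitude, turn-rate magnitude), and replica occupancy (time in the lower
half, time attacking).  Positions are smoothed with a centered moving
average (18 frames at 30 Hz) before differentiation, and velocities are
smoothed again before computing accelerations.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import FRAME_RATE_HZ, Trajectory, TrialRecord
from .states import BehaviorState

__all__ = [
    "moving_average",
    "velocity",
    "speed",
    "accel_magnitude",
    "turn_rate",
    "avoidance_metrics",
    "geotaxis_metrics",
    "count_bottom_entries",
    "robot_occupancy",
    "bin_by_time",
    "compute_metric_table",
    "DEFAULT_SMOOTH_WINDOW",
    "TIME_BINS",
    "TIME_BIN_LABELS",
    "observation_bins",
]

DEFAULT_SMOOTH_WINDOW = 18
_DT = 1.0 / FRAME_RATE_HZ

#: Observation-window time bins (seconds relative to observation start).
TIME_BINS: Tuple[Tuple[float, float], ...] = ((0, 120), (120, 240), (240, 360))
TIME_BIN_LABELS: Tuple[str, ...] = ("0-2", "2-4", "4-6")


def observation_bins(observation_s: float) -> Tuple[tuple, tuple]:
    """Three equal time bins over the observation window, labelled in minutes."""
    edges = [observation_s * k / 3.0 for k in range(4)]
    bins = tuple((edges[k], edges[k + 1]) for k in range(3))
    labels = tuple(f"{t0 / 60:g}-{t1 / 60:g}" for t0, t1 in bins)
    return bins, labels


def _symmetric_kernel(window: int) -> np.ndarray:
    """Centered moving-average kernel; even orders get half-weight end taps.

    An even window w uses w+1 taps with weights (1/2, 1, ..., 1, 1/2)/w so
    the kernel stays symmetric and preserves affine trends exactly.
    """
    if window % 2 == 1:
        return np.full(window, 1.0 / window)
    k = np.ones(window + 1)
    k[0] = k[-1] = 0.5
    return k / window


def moving_average(
    series: Sequence[float], window_frames: int = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Centered moving average; output has the input's length.

    Near the edges the window shrinks symmetrically to the available
    samples, so constants and (interior) affine trends pass through
    unchanged.  ``window_frames`` of 1 (or 0 / None) returns a copy.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not window_frames or window_frames <= 1:
        return x.copy()
    n = x.size
    if window_frames > n:
        raise ValueError(f"window {window_frames} exceeds series length {n}")
    kernel = _symmetric_kernel(window_frames)
    half = (len(kernel) - 1) // 2
    out = np.convolve(x, kernel, mode="same")
    # shrunken symmetric windows at the boundaries
    for t in range(min(half, n)):
        for idx in (t, n - 1 - t):
            h = min(idx, n - 1 - idx)
            if h == 0:
                out[idx] = x[idx]
            else:
                out[idx] = x[idx - h : idx + h + 1] @ _symmetric_kernel(2 * h)
    return out


def _smooth_xyz(traj: Trajectory, window: Optional[int]) -> np.ndarray:
    if not window or window <= 1:
        return traj.xyz.astype(float)
    return np.column_stack([moving_average(traj.xyz[:, k], window) for k in range(3)])


def velocity(
    traj: Trajectory, window: Optional[int] = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """First-difference velocity (cm/s) of the (smoothed) positions; (n-1, 3)."""
    if len(traj) < 2:
        raise ValueError("need at least two samples to differentiate")
    xyz = _smooth_xyz(traj, window)
    return np.diff(xyz, axis=0) * traj.rate_hz


def speed(
    traj: Trajectory, window: Optional[int] = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Speed series (cm/s) from first-order differentiation; length n-1."""
    return np.linalg.norm(velocity(traj, window), axis=1)


def accel_magnitude(
    traj: Trajectory, window: Optional[int] = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Acceleration magnitude (cm/s^2); velocities are re-smoothed first."""
    if len(traj) < 3:
        raise ValueError("need at least three samples for acceleration")
    v = velocity(traj, window)
    if window and window > 1 and v.shape[0] >= window:
        v = np.column_stack([moving_average(v[:, k], window) for k in range(3)])
    return np.linalg.norm(np.diff(v, axis=0) * traj.rate_hz, axis=1)


def turn_rate(
    traj: Trajectory,
    window: Optional[int] = DEFAULT_SMOOTH_WINDOW,
    zero_speed_tol: float = 1e-6,
) -> np.ndarray:
    """Turn-rate magnitude (rad/s): angle between consecutive velocities / dt.

    The cosine is clamped to [-1, 1].  Frames where either velocity is
    below ``zero_speed_tol`` yield NaN (no turn-rate sample); length n-2.
    """
    if len(traj) < 3:
        raise ValueError("need at least three samples for turn rate")
    v = velocity(traj, window)
    v0, v1 = v[:-1], v[1:]
    n0 = np.linalg.norm(v0, axis=1)
    n1 = np.linalg.norm(v1, axis=1)
    ok = (n0 > zero_speed_tol) & (n1 > zero_speed_tol)
    cosang = np.full(v0.shape[0], np.nan)
    dot = np.einsum("ij,ij->i", v0[ok], v1[ok])
    cosang[ok] = np.clip(dot / (n0[ok] * n1[ok]), -1.0, 1.0)
    return np.arccos(cosang) * traj.rate_hz


def _replica_reference(trial: TrialRecord) -> np.ndarray:
    """Per-frame replica reference position over the observation window."""
    if trial.condition == "control":
        center = np.array(trial.arena.lateral_center)
        n = len(trial.fish_observation())
        return np.tile(center, (n, 1))
    return trial.robot_observation().xyz


def avoidance_metrics(trial: TrialRecord) -> Tuple[float, float]:
    """(average fish-replica distance cm, % time in opposite vertical half).

    In the control condition the distance reference is the geometric center
    of the lateral-tank water volume.  The opposite-half percentage adds
    the time the fish spends lower while the replica is upper to the time
    it spends upper while the replica is lower (midline counts as lower).
    """
    fish = trial.fish_observation().xyz
    ref = _replica_reference(trial)
    n = min(len(fish), len(ref))
    fish, ref = fish[:n], ref[:n]
    dist = float(np.linalg.norm(fish - ref, axis=1).mean())
    mid = trial.arena.water_depth_cm / 2.0
    fish_lower = fish[:, 2] <= mid
    robot_lower = ref[:, 2] <= mid
    pct_opposite = float((fish_lower != robot_lower).mean() * 100.0)
    return dist, pct_opposite


def count_bottom_entries(z: np.ndarray, threshold: float) -> int:
    """Count crossings from z >= threshold to z < threshold."""
    below = np.asarray(z) < threshold
    return int(np.sum(~below[:-1] & below[1:]))


def geotaxis_metrics(
    trial: TrialRecord, window: Optional[int] = DEFAULT_SMOOTH_WINDOW
) -> Tuple[float, float, int]:
    """(avg height cm, % time in the bottom third, entries into the bottom).

    The bottom section is the bottom third of the water column (5 cm at the
    default 15 cm depth); an entry is a crossing into it between
    consecutive smoothed samples.
    """
    z = trial.fish_observation().z
    zs = moving_average(z, window) if window and window > 1 else z
    thr = trial.arena.water_depth_cm / 3.0
    return (
        float(zs.mean()),
        float((zs < thr).mean() * 100.0),
        count_bottom_entries(zs, thr),
    )


def robot_occupancy(trial: TrialRecord) -> pd.DataFrame:
    """Per-bin replica occupancy: % time in the lower half, % time attacking.

    Undefined in the control condition (no replica): returns NaN values.
    """
    bins, labels = observation_bins(trial.observation_s)
    rows = []
    if trial.condition == "control":
        for label in labels:
            rows.append({"time_bin": label, "pct_robot_lower_half": np.nan,
                         "pct_robot_attacking": np.nan})
        return pd.DataFrame(rows)
    robot = trial.robot_observation()
    t_rel = robot.t_s - trial.habituation_s
    lower = robot.z <= trial.arena.water_depth_cm / 2.0
    states = trial.observation_states()
    attacking = np.array([s is BehaviorState.A for s in states])
    state_t = np.arange(len(states), dtype=float)
    for (t0, t1), label in zip(bins, labels):
        frame_mask = (t_rel >= t0) & (t_rel < t1)
        state_mask = (state_t >= t0) & (state_t < t1)
        rows.append(
            {
                "time_bin": label,
                "pct_robot_lower_half": float(lower[frame_mask].mean() * 100.0),
                "pct_robot_attacking": float(attacking[state_mask].mean() * 100.0),
            }
        )
    return pd.DataFrame(rows)


def bin_by_time(
    t_rel: np.ndarray,
    values: np.ndarray,
    bins: Tuple[Tuple[float, float], ...] = TIME_BINS,
) -> list:
    """Mean of ``values`` within each [t0, t1) bin (NaN samples ignored)."""
    t_rel = np.asarray(t_rel, dtype=float)
    values = np.asarray(values, dtype=float)
    out = []
    for t0, t1 in bins:
        sel = values[(t_rel >= t0) & (t_rel < t1)]
        sel = sel[~np.isnan(sel)]
        out.append(float(sel.mean()) if sel.size else np.nan)
    return out


def compute_metric_table(
    trial: TrialRecord, window: Optional[int] = DEFAULT_SMOOTH_WINDOW
) -> pd.DataFrame:
    """All nine dependent measures per 2-min bin; one row per (trial, bin)."""
    fish = trial.fish_observation()
    t_rel = fish.t_s - trial.habituation_s
    ref = _replica_reference(trial)
    n = min(len(fish), len(ref))

    dist = np.linalg.norm(fish.xyz[:n] - ref[:n], axis=1)
    mid = trial.arena.water_depth_cm / 2.0
    opposite = ((fish.z[:n] <= mid) != (ref[:n, 2] <= mid)).astype(float) * 100.0

    zs = moving_average(fish.z, window) if window and window > 1 else fish.z
    thr = trial.arena.water_depth_cm / 3.0
    bottom = (zs < thr).astype(float) * 100.0

    spd = speed(fish, window)
    acc = accel_magnitude(fish, window)
    omega = turn_rate(fish, window)

    occupancy = robot_occupancy(trial)
    bins, labels = observation_bins(trial.observation_s)
    rows = []
    for i, ((t0, t1), label) in enumerate(zip(bins, labels)):
        frame = (t_rel >= t0) & (t_rel < t1)
        below = zs < thr
        enter = ~below[:-1] & below[1:] & frame[1:]
        rows.append(
            {
                "trial_id": trial.trial_id,
                "condition": trial.condition,
                "time_bin": label,
                "avg_distance_to_replica_cm": bin_by_time(t_rel[:n], dist, ((t0, t1),))[0],
                "pct_time_opposite_half": bin_by_time(t_rel[:n], opposite, ((t0, t1),))[0],
                "avg_height_cm": bin_by_time(t_rel, zs, ((t0, t1),))[0],
                "pct_time_bottom_third": bin_by_time(t_rel, bottom, ((t0, t1),))[0],
                "n_entries_bottom": int(enter.sum()),
                "avg_speed_cm_s": bin_by_time(t_rel[:-1], spd, ((t0, t1),))[0],
                "avg_accel_mag_cm_s2": bin_by_time(t_rel[1:-1], acc, ((t0, t1),))[0],
                "avg_turn_rate_rad_s": bin_by_time(t_rel[:-2], omega, ((t0, t1),))[0],
                "pct_robot_lower_half": occupancy.loc[i, "pct_robot_lower_half"],
                "pct_robot_attacking": occupancy.loc[i, "pct_robot_attacking"],
            }
        )
    return pd.DataFrame(rows)
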