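"""Trajectory processing and kinematic performance metrics.

Raw effector streams (30 Hz, mm, origin at the resting position) are
smoothed with a 5-sample moving average, resampled uniformly in arc
length, and reduced to per-trial summaries: movement onset, completion,
the endpoint at the target radial distance, the signed motor-performance
compensation angle, reaching error/variability, and timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .task_design import (
    Mode,
    TaskGeometry,
    TrialSpec,
    bearing_deg,
    target_bearing,
    target_positions,
)


class TrajectoryError(ValueError):
    """Raised for trajectories that violate an operation's preconditions."""


class IncompleteReachError(TrajectoryError):
    """Trajectory never reaches the target radial distance."""


@dataclass
class Trajectory:
    """Time-stamped 2-D effector samples for a single trial."""

    t: np.ndarray  # seconds, strictly increasing
    xy: np.ndarray  # shape (n, 2), millimetres
    trial: Optional[TrialSpec] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise TrajectoryError("xy must have shape (n, 2)")
        if len(self.t) != len(self.xy):
            raise TrajectoryError("t and xy must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise TrajectoryError("timestamps must be strictly increasing")

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.xy[:, 0], self.xy[:, 1])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class KinematicSummary:
    """Per-trial kinematic metrics."""

    onset_time_s: float
    reaching_time_s: float
    endpoint_mm: tuple[float, float]
    endpoint_angle_error_deg: float
    mp_compensation_deg: float
    reach_error_mm: float
    completed: bool
    restarted: bool
    completion_time_s: float = field(default=np.nan)


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_trajectory(traj: Trajectory, window: int = 5) -> Trajectory:
    """Moving-average smoothing only, original timestamps preserved."""
    if len(traj) < window:
        raise TrajectoryError(
            f"trajectory too short to smooth (need >= {window} samples)"
        )
    return Trajectory(
        t=traj.t.copy(),
        xy=np.column_stack(
            [moving_average(traj.xy[:, 0], window), moving_average(traj.xy[:, 1], window)]
        ),
        trial=traj.trial,
    )


def smooth_and_resample(traj: Trajectory, n_points: int = 100) -> Trajectory:
    """5-sample moving average, then arc-length-uniform resampling.

    The smoothed path is linearly interpolated at `n_points` positions
    uniformly spaced in cumulative arc length; timestamps are carried
    through the same interpolation.
    """
    if len(traj) < 5:
        raise TrajectoryError("trajectory too short to smooth (need >= 5 samples)")
    sx = moving_average(traj.xy[:, 0])
    sy = moving_average(traj.xy[:, 1])
    steps = np.hypot(np.diff(sx), np.diff(sy))
    s = np.concatenate([[0.0], np.cumsum(steps)])
    if s[-1] == 0:  # no net movement: resample in time instead
        grid_t = np.linspace(traj.t[0], traj.t[-1], n_points)
        return Trajectory(
            t=grid_t,
            xy=np.column_stack(
                [np.interp(grid_t, traj.t, sx), np.interp(grid_t, traj.t, sy)]
            ),
            trial=traj.trial,
        )
    # make arc length strictly increasing for interpolation (drop dwell samples)
    keep = np.concatenate([[True], steps > 0])
    s_u, sx_u, sy_u, t_u = s[keep], sx[keep], sy[keep], traj.t[keep]
    grid = np.linspace(0.0, s_u[-1], n_points)
    return Trajectory(
        t=np.interp(grid, s_u, t_u),
        xy=np.column_stack([np.interp(grid, s_u, sx_u), np.interp(grid, s_u, sy_u)]),
        trial=traj.trial,
    )


def radial_velocity(traj: Trajectory) -> np.ndarray:
    """Radial speed (mm/s) from first differences; first sample gets 0."""
    r = traj.radius
    dt = np.diff(traj.t)
    v = np.abs(np.diff(r)) / dt
    return np.concatenate([[0.0], v])


def detect_onset(traj: Trajectory, threshold_fraction: float = 0.02) -> float:
    """Movement onset: first sample whose radial velocity exceeds
    `threshold_fraction` of the maximum radial velocity."""
    v = radial_velocity(traj)
    vmax = v.max()
    if vmax == 0:
        raise TrajectoryError("no movement detected (all-zero radial velocity)")
    idx = int(np.argmax(v > threshold_fraction * vmax))
    return float(traj.t[idx])


def detect_completion(
    traj: Trajectory,
    still_window_s: float = 0.5,
    still_displacement_mm: float = 0.5,
    min_path_mm: float = 50.0,
) -> tuple[bool, float]:
    """Completion: the effector moved less than `still_displacement_mm`
    over a `still_window_s` window after travelling more than
    `min_path_mm` from the start. Returns (completed, completion_time);
    completion_time is NaN when the criterion is never met."""
    steps = np.hypot(np.diff(traj.xy[:, 0]), np.diff(traj.xy[:, 1]))
    path = np.concatenate([[0.0], np.cumsum(steps)])
    n = len(traj)
    for i in range(n):
        if path[i] <= min_path_mm:
            continue
        j = int(np.searchsorted(traj.t, traj.t[i] - still_window_s, side="left"))
        if traj.t[i] - traj.t[j] < still_window_s - 1e-9:
            continue
        if path[i] - path[j] < still_displacement_mm:
            return True, float(traj.t[i])
    return False, float("nan")


def _first_radius_crossing(traj: Trajectory, radius_mm: float) -> tuple[np.ndarray, float]:
    """Linearly interpolated point and time of the first outward crossing."""
    r = traj.radius
    beyond = r >= radius_mm
    if not beyond.any():
        raise IncompleteReachError(
            f"trajectory never reaches radial distance {radius_mm:.1f} mm"
        )
    k = int(np.argmax(beyond))
    if k == 0:
        return traj.xy[0].copy(), float(traj.t[0])
    f = (radius_mm - r[k - 1]) / (r[k] - r[k - 1])
    point = traj.xy[k - 1] + f * (traj.xy[k] - traj.xy[k - 1])
    return point, float(traj.t[k - 1] + f * (traj.t[k] - traj.t[k - 1]))


def endpoint_at_radius(traj: Trajectory, geometry: TaskGeometry) -> np.ndarray:
    """Effector position at the first crossing of the target radial
    distance (linear interpolation between the bracketing samples)."""
    point, _ = _first_radius_crossing(traj, geometry.target_radius_mm)
    # place exactly on the circle (removes the chord-interpolation residual)
    return point * (geometry.target_radius_mm / np.hypot(*point))


def crossing_time_at_radius(traj: Trajectory, geometry: TaskGeometry) -> float:
    _, t = _first_radius_crossing(traj, geometry.target_radius_mm)
    return t


def _wrap_deg(a: float) -> float:
    return float((a + 180.0) % 360.0 - 180.0)


def mp_compensation(
    traj: Trajectory, trial: TrialSpec, geometry: TaskGeometry
) -> float:
    """Motor-performance compensation angle, degrees.

    Signed angle between the target bearing and the bearing of
    (endpoint - deviation-onset crossing point), with positive sign when
    the movement opposes the imposed rotation; a fully compensating
    reach under deviation alpha reads +|alpha|. For control trials the
    signed endpoint bearing error is returned (positive = clockwise of
    the target), which is the MP baseline.
    """
    onset_point, _ = _first_radius_crossing(traj, geometry.deviation_onset_mm)
    endpoint = endpoint_at_radius(traj, geometry)
    seg = endpoint - onset_point
    b = float(bearing_deg(seg[0], seg[1]))
    theta_t = target_bearing(geometry, trial.target_side)
    if trial.mode == Mode.CONTROL:
        return _wrap_deg(b - theta_t)
    return float(np.sign(trial.deviation_deg)) * _wrap_deg(theta_t - b)


def endpoint_angle_error(
    traj: Trajectory, trial: TrialSpec, geometry: TaskGeometry
) -> float:
    """Unsigned bearing error (deg) of the endpoint relative to the target."""
    endpoint = endpoint_at_radius(traj, geometry)
    b = float(bearing_deg(endpoint[0], endpoint[1]))
    return abs(_wrap_deg(b - target_bearing(geometry, trial.target_side)))


def detect_restart(
    traj: Trajectory,
    geometry: TaskGeometry,
    out_fraction: float = 0.3,
    back_fraction: float = 0.1,
) -> bool:
    """A trial is a restart when the radial distance, after exceeding
    `out_fraction` of the target radius, falls back below `back_fraction`
    before the reach completes. Restarted trials are excluded upstream."""
    r = traj.radius
    rt = geometry.target_radius_mm
    went_out = False
    for ri in r:
        if ri > out_fraction * rt:
            went_out = True
        elif went_out and ri < back_fraction * rt:
            return True
    return False


def reach_metrics(
    endpoints: np.ndarray, target: np.ndarray
) -> tuple[float, float]:
    """Accuracy and precision of a set of reach endpoints.

    Returns (error, variability): the mean Euclidean endpoint-to-target
    distance and the n-1 standard deviation of those distances, both mm.
    """
    endpoints = np.atleast_2d(np.asarray(endpoints, dtype=float))
    if len(endpoints) < 2:
        raise ValueError("need at least 2 endpoints for reach metrics")
    d = np.hypot(*(endpoints - np.asarray(target, dtype=float)).T)
    return float(d.mean()), float(d.std(ddof=1))


def timing(
    traj: Trajectory,
    geometry: TaskGeometry,
    end_rule: str = "stillness",
    onset_threshold_fraction: float = 0.02,
) -> tuple[float, float, bool]:
    """(onset_time, reaching_time, completed) for one trial.

    `end_rule` is the definition of end of trial: "stillness" (default,
    the blind-reaching completion rule) or "radius" (first crossing of
    the target radial distance).
    """
    onset = detect_onset(traj, onset_threshold_fraction)
    if end_rule == "radius":
        try:
            end = crossing_time_at_radius(traj, geometry)
            completed = True
        except IncompleteReachError:
            return onset, float("nan"), False
    else:
        completed, end = detect_completion(traj)
        if not completed:
            return onset, float("nan"), False
    return onset, float(end - onset), completed


def summarize_trial(
    traj: Trajectory,
    trial: TrialSpec,
    geometry: TaskGeometry,
    smooth: bool = True,
    end_rule: str = "stillness",
) -> KinematicSummary:
    """Full kinematic summary of one trial (smoothed by default).

    Metrics are computed on the smoothed stream at its native sampling;
    arc-length resampling (`smooth_and_resample`) is reserved for
    averaging trajectories across trials.
    """
    proc = smooth_trajectory(traj) if smooth else traj
    restarted = detect_restart(proc, geometry)
    onset, reaching, completed = timing(proc, geometry, end_rule=end_rule)
    _, completion_t = detect_completion(proc)
    endpoint = endpoint_at_radius(proc, geometry)
    target = target_positions(geometry)[trial.target_side]
    return KinematicSummary(
        onset_time_s=onset,
        reaching_time_s=reaching,
        endpoint_mm=(float(endpoint[0]), float(endpoint[1])),
        endpoint_angle_error_deg=endpoint_angle_error(proc, trial, geometry),
        mp_compensation_deg=mp_compensation(proc, trial, geometry),
        reach_error_mm=float(np.hypot(*(endpoint - target))),
        completed=completed,
        restarted=restarted,
        completion_time_s=completion_t,
    )
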