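"""Ground-truth walker kinematics for a straight-path, there-and-back gait trial.

The simulated protocol mirrors a standard clinical gait-speed measurement: a
walker covers a straight ~7 m path instrumented with a pressure-sensitive
walkway over the middle 5 m, completing three there-and-back round trips (six
walks) at a nominal steady pace and pausing ~2 s at each turnaround.  Speed
follows a trapezoidal profile — constant acceleration from rest, a steady-speed
plateau, constant deceleration to rest at the far end — so that the walkway
zone is crossed at (nearly) constant speed, as in the real protocol where the
turning points sit ~1 m beyond the mat precisely to push the acceleration and
deceleration phases off the measurement zone.

The :class:`Trajectory` produced here is the single source of ground truth
from which every sensor observation in :mod:`gaitsense.sensors` is derived.
Positions are metres along the path measured from the walker's start point X1;
velocity is the signed time-derivative of position (positive = away from the
start / radar end).  Time is a uniform grid and intervals are half-open
``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "WalkProtocol",
    "SpeedProfile",
    "Trajectory",
    "GroundTruth",
    "build_speed_profile",
    "simulate_trajectory",
    "mat_segment_intervals",
    "walk_spans",
    "cw_observation_windows",
    "off_mat_time_per_round_trip",
]


class _FrozenModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class WalkProtocol(_FrozenModel):
    """Geometry and timing of the walking protocol.

    Parameters
    ----------
    path_length
        Full walk distance in metres (start point X1 to turning point X2).
    mat_length
        Length of the walkway measurement zone, metres.
    mat_start_offset
        Distance from X1 to the start of the measurement zone, metres.
    n_round_trips
        Number of there-and-back round trips; each contributes two walks.
    turnaround_dwell
        Stationary pause at each turnaround, seconds.
    sensor_positions
        Optional map of sensor name -> position (metres on the path axis,
        measured from X1; negative values sit behind the start point).  The
        radars default to -1 m (1 m behind X1) and the thermal camera to 1 m
        beyond the far turning point.
    """

    path_length: float = Field(default=7.0, gt=0)
    mat_length: float = Field(default=5.0, gt=0)
    mat_start_offset: float = Field(default=1.0, ge=0)
    n_round_trips: int = Field(default=3, ge=1)
    turnaround_dwell: float = Field(default=2.0, ge=0)
    sensor_positions: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_geometry(self) -> "WalkProtocol":
        if self.path_length < self.mat_start_offset + self.mat_length:
            raise ValueError(
                "path_length must cover mat_start_offset + mat_length "
                f"({self.path_length} < {self.mat_start_offset + self.mat_length})"
            )
        return self

    @property
    def n_walks(self) -> int:
        return 2 * self.n_round_trips

    @property
    def mat_zone(self) -> tuple[float, float]:
        """(lo, hi) positions of the measurement zone along the path."""
        return (self.mat_start_offset, self.mat_start_offset + self.mat_length)

    @property
    def radar_position(self) -> float:
        return self.sensor_positions.get("radar", -1.0)

    @property
    def camera_position(self) -> float:
        return self.sensor_positions.get("thermal", self.path_length + 1.0)


class SpeedProfile(_FrozenModel):
    """Trapezoidal speed profile: ramp up, steady plateau, ramp down.

    ``accel`` is the magnitude used for both the acceleration and the
    deceleration ramp.  A plateau must exist on the path the profile is used
    with, i.e. ``2 * steady_speed**2 / (2 * accel) < path_length``.
    """

    steady_speed: float = Field(gt=0)
    accel: float = Field(gt=0)
    pace_label: str = "normal"

    @property
    def ramp_distance(self) -> float:
        """Distance covered by one ramp, v^2 / (2a), metres."""
        return self.steady_speed**2 / (2.0 * self.accel)

    @property
    def ramp_time(self) -> float:
        """Duration of one ramp, v / a, seconds."""
        return self.steady_speed / self.accel

    def feasible_for(self, path_length: float) -> bool:
        return 2.0 * self.ramp_distance < path_length

    def walk_duration(self, path_length: float) -> float:
        """Total time for one walk of ``path_length`` metres."""
        return path_length / self.steady_speed + self.steady_speed / self.accel

    def plateau_interval(self, path_length: float) -> tuple[float, float]:
        """Positions (metres from the walk's own start) held at steady speed."""
        return (self.ramp_distance, path_length - self.ramp_distance)

    # -- closed-form kinematics (tau measured from the start of one walk) --

    def distance_at(self, tau: np.ndarray | float, path_length: float) -> np.ndarray:
        v, a, L = self.steady_speed, self.accel, path_length
        tau = np.asarray(tau, dtype=float)
        d, tr, T = self.ramp_distance, self.ramp_time, self.walk_duration(L)
        s = np.where(
            tau < tr,
            0.5 * a * tau**2,
            np.where(
                tau < T - tr,
                d + v * (tau - tr),
                L - 0.5 * a * np.clip(T - tau, 0.0, None) ** 2,
            ),
        )
        return np.clip(s, 0.0, L)

    def speed_at(self, tau: np.ndarray | float, path_length: float) -> np.ndarray:
        v, a, L = self.steady_speed, self.accel, path_length
        tau = np.asarray(tau, dtype=float)
        tr, T = self.ramp_time, self.walk_duration(L)
        s = np.where(
            tau < tr,
            a * tau,
            np.where(tau < T - tr, v, a * np.clip(T - tau, 0.0, None)),
        )
        return np.clip(s, 0.0, v)

    def time_at_distance(self, p: float, path_length: float) -> float:
        """Time (within one walk) at which ``p`` metres have been covered."""
        v, a, L = self.steady_speed, self.accel, path_length
        if not 0.0 <= p <= L:
            raise ValueError(f"distance {p} outside [0, {L}]")
        d, tr, T = self.ramp_distance, self.ramp_time, self.walk_duration(L)
        if p <= d:
            return float(np.sqrt(2.0 * p / a))
        if p < L - d:
            return tr + (p - d) / v
        return T - float(np.sqrt(2.0 * (L - p) / a))


def build_speed_profile(
    pace_label: str,
    steady_speed: float,
    accel: float = 0.5,
    path_length: float = 7.0,
) -> SpeedProfile:
    """Construct a trapezoidal speed profile, rejecting infeasible ones.

    Raises
    ------
    ValueError
        If the acceleration and deceleration ramps together exceed the path,
        so no steady-speed plateau exists.
    """
    profile = SpeedProfile(steady_speed=steady_speed, accel=accel, pace_label=pace_label)
    if not profile.feasible_for(path_length):
        raise ValueError(
            f"no steady-speed plateau: ramps of {profile.ramp_distance:.2f} m each "
            f"do not fit a {path_length:.2f} m path"
        )
    return profile


@dataclass
class Trajectory:
    """Time-stamped walker state on a uniform grid.

    ``walk_index`` is 0..n_walks-1 during walks and -1 during turnaround
    dwells.  Even walks move away from the start (velocity > 0), odd walks
    return (velocity < 0).
    """

    sample_rate: float
    times: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    walk_index: np.ndarray

    @property
    def n_walks(self) -> int:
        return int(self.walk_index.max()) + 1

    @property
    def duration(self) -> float:
        return float(self.times[-1])


@dataclass
class GroundTruth:
    """Per-walk truth extracted from the protocol in closed form.

    ``mat_intervals`` are half-open [t_enter, t_exit) spans during which the
    walker is inside the measurement zone; ``trial_mean_speed`` is the mean of
    the per-walk mat-segment speeds (mat_length / crossing duration), i.e.
    exactly the quantity the walkway reference measures.
    """

    per_walk_steady_speed: list[float]
    mat_intervals: list[tuple[float, float] | None]
    trial_mean_speed: float
    mat_segment_speeds: list[float] = field(default_factory=list)


def simulate_trajectory(
    protocol: WalkProtocol,
    profile: SpeedProfile,
    sample_rate: float = 1000.0,
) -> tuple[Trajectory, GroundTruth]:
    """Deterministically simulate the full multi-walk trajectory.

    The timeline is: walk 0, dwell, walk 1, dwell, ..., walk n-1 (no trailing
    dwell).  Within each walk the closed-form trapezoidal kinematics are
    evaluated directly on the time grid, so there is no integration drift.
    """
    if not profile.feasible_for(protocol.path_length):
        raise ValueError("speed profile infeasible for this path length")
    L = protocol.path_length
    n_walks = protocol.n_walks
    T_walk = profile.walk_duration(L)
    dwell = protocol.turnaround_dwell
    cycle = T_walk + dwell
    total = n_walks * T_walk + (n_walks - 1) * dwell

    n = int(round(total * sample_rate)) + 1
    times = np.arange(n) / sample_rate
    k = np.minimum(np.floor(times / cycle).astype(int), n_walks - 1)
    tau = times - k * cycle
    in_walk = tau <= T_walk + 0.5 / sample_rate

    s = profile.distance_at(np.clip(tau, 0.0, T_walk), L)
    spd = profile.speed_at(np.clip(tau, 0.0, T_walk), L)
    s = np.where(in_walk, s, L)  # dwelling at the far end of walk k
    spd = np.where(in_walk, spd, 0.0)

    even = (k % 2) == 0
    position = np.where(even, s, L - s)
    velocity = np.where(even, spd, -spd)
    walk_index = np.where(in_walk, k, -1)

    traj = Trajectory(
        sample_rate=float(sample_rate),
        times=times,
        position=position,
        velocity=velocity,
        walk_index=walk_index.astype(int),
    )

    # Closed-form mat crossings: outbound walks cross lo then hi, inbound
    # walks cross (L - hi) then (L - lo) of their own distance coordinate.
    lo, hi = protocol.mat_zone
    t_out = (profile.time_at_distance(lo, L), profile.time_at_distance(hi, L))
    t_in = (
        profile.time_at_distance(L - hi, L),
        profile.time_at_distance(L - lo, L),
    )
    intervals: list[tuple[float, float] | None] = []
    speeds: list[float] = []
    for w in range(n_walks):
        start = w * cycle
        a, b = t_out if w % 2 == 0 else t_in
        intervals.append((start + a, start + b))
        speeds.append(protocol.mat_length / (b - a))
    gt = GroundTruth(
        per_walk_steady_speed=[profile.steady_speed] * n_walks,
        mat_intervals=intervals,
        trial_mean_speed=float(np.mean(speeds)),
        mat_segment_speeds=speeds,
    )
    return traj, gt


def walk_spans(traj: Trajectory) -> list[tuple[float, float]]:
    """Half-open [t_start, t_stop) time span of each walk segment."""
    dt = 1.0 / traj.sample_rate
    spans = []
    for w in range(traj.n_walks):
        t = traj.times[traj.walk_index == w]
        spans.append((float(t[0]), float(t[-1]) + dt))
    return spans


def mat_segment_intervals(
    traj: Trajectory, protocol: WalkProtocol
) -> list[tuple[float, float] | None]:
    """Per-walk half-open spans during which the walker is on the mat zone.

    A walk that never enters the zone yields ``None`` (flagged empty).
    """
    lo, hi = protocol.mat_zone
    dt = 1.0 / traj.sample_rate
    out: list[tuple[float, float] | None] = []
    for w in range(protocol.n_walks):
        mask = (traj.walk_index == w) & (traj.position >= lo) & (traj.position <= hi)
        if not mask.any():
            out.append(None)
            continue
        t = traj.times[mask]
        out.append((float(t[0]), float(t[-1]) + dt))
    return out


def cw_observation_windows(
    traj: Trajectory,
    protocol: WalkProtocol,
    fov_range: float,
    mode: str = "primary",
    radar_position: float | None = None,
    speed_fraction: float = 0.95,
) -> list[tuple[float, float] | None]:
    """Per-walk analysis windows for the CW Doppler estimator.

    ``primary`` windows span the whole walk.  ``secondary`` windows keep only
    the constant-speed points inside the radar's usable field of view while
    the walker is on the mat zone — the sub-interval a mat-aligned analysis
    would use.  Constant speed means |velocity| within ``speed_fraction`` of
    the walk's own maximum.
    """
    if mode == "primary":
        return list(walk_spans(traj))
    if mode != "secondary":
        raise ValueError(f"unknown mode {mode!r}")
    rpos = protocol.radar_position if radar_position is None else radar_position
    lo, hi = protocol.mat_zone
    dt = 1.0 / traj.sample_rate
    rng_ok = np.abs(traj.position - rpos) <= fov_range
    on_mat = (traj.position >= lo) & (traj.position <= hi)
    out: list[tuple[float, float] | None] = []
    for w in range(protocol.n_walks):
        in_walk = traj.walk_index == w
        vmax = np.abs(traj.velocity[in_walk]).max()
        steady = np.abs(traj.velocity) >= speed_fraction * vmax
        mask = in_walk & rng_ok & on_mat & steady
        if not mask.any():
            out.append(None)
            continue
        t = traj.times[mask]
        out.append((float(t[0]), float(t[-1]) + dt))
    return out


def off_mat_time_per_round_trip(protocol: WalkProtocol, profile: SpeedProfile) -> float:
    """Time per round trip the walker spends off the mat zone, seconds.

    A round trip lasts two walks plus two turnaround dwells; subtracting the
    two mat crossings leaves the off-mat episodes (the turnarounds and the
    short path segments beyond the zone).  Used as the timing correction for
    the thermal-camera mat-equivalent analysis.
    """
    L = protocol.path_length
    lo, hi = protocol.mat_zone
    T_rt = 2.0 * profile.walk_duration(L) + 2.0 * protocol.turnaround_dwell
    on_out = profile.time_at_distance(hi, L) - profile.time_at_distance(lo, L)
    on_in = profile.time_at_distance(L - lo, L) - profile.time_at_distance(L - hi, L)
    return T_rt - on_out - on_in
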