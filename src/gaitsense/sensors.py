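"""Forward models mapping a walker trajectory to synthetic sensor observations.

Five modalities are modelled, each with controllable noise and bit-reproducible
output under a fixed seed:

* **CW radar** — a 24-GHz continuous-wave radar sees the walker as a complex
  baseband tone whose instantaneous frequency is the (two-way) Doppler shift
  2 v f0 / c; amplitude falls off as range^-k and is strongly attenuated
  beyond the usable field of view.
* **UWB radar** — a pulsed ultra-wideband radar returns one range profile per
  pulse; the walker appears as a Gaussian-shaped echo in the bin containing
  its range, on top of a static clutter profile.  A target-free background
  capture accompanies the stack for clutter subtraction.
* **Thermal camera** — low-resolution frames of a warm Gaussian blob against
  a cooler background; the blob's pixel radius grows as 1/range with constant
  peak intensity, so the per-frame intensity sum grows as the walker
  approaches.
* **Motion-capture suit** — 125 fps 3-D head coordinates with additive
  positional noise.
* **Pressure walkway** — timed footfall records (heel, toe, contact time) on
  the mat's active area, with spatial jitter, 60 Hz time quantisation, and an
  optional "light step" corruption that halves or doubles a walk's apparent
  speed to exercise the reference's outlier-omission rule.

All simulators take ``(trajectory, protocol, config, seed)`` and are pure
functions of those inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .walker import Trajectory, WalkProtocol

__all__ = [
    "CWRadarConfig",
    "CWSignal",
    "UWBConfig",
    "RangeProfileStack",
    "ThermalConfig",
    "ThermalFrames",
    "MocapConfig",
    "HeadTrack",
    "GaitRiteConfig",
    "Footfall",
    "FootfallSequence",
    "simulate_cw_signal",
    "simulate_uwb_stack",
    "simulate_thermal_frames",
    "simulate_mocap",
    "simulate_footfalls",
]

SPEED_OF_LIGHT = 2.998e8  # m/s


class _FrozenModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


# --------------------------------------------------------------------------
# continuous-wave Doppler radar
# --------------------------------------------------------------------------


class CWRadarConfig(_FrozenModel):
    """24-GHz continuous-wave radar parameters.

    ``doppler_two_way=True`` applies the monostatic two-way phase
    4*pi*r/lambda; ``False`` uses the one-way 2*pi*r/lambda.  Received
    amplitude falls as range**-amplitude_decay_exponent and is exponentially
    attenuated beyond ``fov_range`` at ``fov_attenuation_rate`` nepers/m.
    """

    f0: float = Field(default=24e9, gt=0)
    c: float = Field(default=SPEED_OF_LIGHT, gt=0)
    sample_rate: float = Field(default=1000.0, gt=0)
    noise_sd: float = Field(default=0.02, ge=0)
    amplitude_decay_exponent: float = Field(default=2.0, ge=0)
    fov_range: float = Field(default=3.5, gt=0)
    fov_attenuation_rate: float = Field(default=3.0, ge=0)
    doppler_two_way: bool = True

    @property
    def wavelength(self) -> float:
        return self.c / self.f0


@dataclass
class CWSignal:
    """Complex baseband CW radar time series."""

    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0


def simulate_cw_signal(
    traj: Trajectory,
    protocol: WalkProtocol,
    cfg: CWRadarConfig,
    seed: int | np.random.SeedSequence | None = 0,
) -> CWSignal:
    """Synthesize the baseband return of a CW radar watching the walker.

    The baseband sample is ``A(r) * exp(-1j * phi(r))`` with
    ``phi = 4*pi*r/lambda`` (two-way), so a walker approaching the radar
    (range decreasing) produces a positive instantaneous frequency of
    ``2 * v_radial * f0 / c``.

    Raises
    ------
    ValueError
        If the target range reaches zero (collision with the radar) or the
        trajectory rate is not an integer multiple of the radar sample rate.
    """
    step = traj.sample_rate / cfg.sample_rate
    if abs(step - round(step)) > 1e-9 or step < 1 - 1e-9:
        raise ValueError(
            "trajectory sample rate must be an integer multiple of the radar rate"
        )
    pos = traj.position[:: int(round(step))]
    r = np.abs(pos - protocol.radar_position)
    if np.any(r < 1e-9):
        raise ValueError("target range reached zero (collision with radar)")

    k = 4.0 if cfg.doppler_two_way else 2.0
    phase = k * np.pi * r / cfg.wavelength
    amp = r**-cfg.amplitude_decay_exponent
    amp = amp * np.exp(-cfg.fov_attenuation_rate * np.clip(r - cfg.fov_range, 0.0, None))
    rng = np.random.default_rng(seed)
    noise = cfg.noise_sd * (
        rng.standard_normal(r.size) + 1j * rng.standard_normal(r.size)
    ) / np.sqrt(2.0)
    samples = amp * np.exp(-1j * phase) + noise
    return CWSignal(sample_rate=cfg.sample_rate, samples=samples, start_time=float(traj.times[0]))


# --------------------------------------------------------------------------
# pulsed ultra-wideband radar
# --------------------------------------------------------------------------


class UWBConfig(_FrozenModel):
    """Pulsed UWB radar parameters.

    The target echo is a Gaussian across range bins, centred on the bin
    containing the target range, with standard deviation
    ``echo_width_bins / 2`` bins and peak amplitude range**-k (unit amplitude
    at 1 m).  ``clutter_amplitude`` scales a smooth static clutter profile
    generated per trial (or pass ``clutter_profile`` explicitly).
    """

    pulse_repetition_rate: float = Field(default=100.0, gt=0)
    range_bin_width: float = Field(default=0.05, gt=0)
    max_range: float = Field(default=10.0, gt=0)
    clutter_amplitude: float = Field(default=0.02, ge=0)
    clutter_profile: list[float] | None = None
    noise_sd: float = Field(default=0.002, ge=0)
    echo_width_bins: int = Field(default=3, ge=1)
    amplitude_decay_exponent: float = Field(default=2.0, ge=0)

    @model_validator(mode="after")
    def _check_bins(self) -> "UWBConfig":
        n = self.max_range / self.range_bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("max_range must be an integer number of range bins")
        if self.clutter_profile is not None and len(self.clutter_profile) != int(round(n)):
            raise ValueError("clutter_profile length must equal the number of range bins")
        return self

    @property
    def n_bins(self) -> int:
        return int(round(self.max_range / self.range_bin_width))


@dataclass
class RangeProfileStack:
    """Stacked per-pulse range profiles plus a target-free background."""

    pulse_times: np.ndarray
    bins: np.ndarray  # range-bin centre positions, metres
    amplitudes: np.ndarray  # (pulses, bins), non-negative
    background: np.ndarray  # (bins,), captured with no target


def _default_clutter(cfg: UWBConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth non-negative static clutter profile."""
    raw = rng.standard_normal(cfg.n_bins)
    win = np.hanning(9)
    smooth = np.convolve(raw, win / win.sum(), mode="same")
    return cfg.clutter_amplitude * np.abs(smooth)


def simulate_uwb_stack(
    traj: Trajectory,
    protocol: WalkProtocol,
    cfg: UWBConfig,
    seed: int | np.random.SeedSequence | None = 0,
) -> RangeProfileStack:
    """Synthesize a pulses x range-bins amplitude matrix for the walk trial.

    Pulses beyond ``max_range`` simply omit the echo (not an error).  The
    ``background`` vector holds the clutter profile plus independent noise,
    emulating the target-free capture taken before the trial.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_clutter, rng_noise, rng_bg = (np.random.default_rng(s) for s in ss.spawn(3))

    pulse_times = np.arange(0.0, traj.duration, 1.0 / cfg.pulse_repetition_rate)
    pos = np.interp(pulse_times, traj.times, traj.position)
    r = np.abs(pos - protocol.radar_position)

    bins = (np.arange(cfg.n_bins) + 0.5) * cfg.range_bin_width
    clutter = (
        np.asarray(cfg.clutter_profile, dtype=float)
        if cfg.clutter_profile is not None
        else _default_clutter(cfg, rng_clutter)
    )

    sigma = cfg.echo_width_bins * cfg.range_bin_width / 2.0
    peak = np.where(r > 1e-9, np.minimum(r, np.inf) ** -cfg.amplitude_decay_exponent, 0.0)
    peak = np.where(r <= cfg.max_range, peak, 0.0)
    echo = peak[:, None] * np.exp(-0.5 * ((bins[None, :] - r[:, None]) / sigma) ** 2)

    amplitudes = clutter[None, :] + echo
    if cfg.noise_sd > 0:
        amplitudes = amplitudes + cfg.noise_sd * rng_noise.standard_normal(amplitudes.shape)
    background = clutter + cfg.noise_sd * rng_bg.standard_normal(cfg.n_bins)
    return RangeProfileStack(
        pulse_times=pulse_times,
        bins=bins,
        amplitudes=np.clip(amplitudes, 0.0, None),
        background=np.clip(background, 0.0, None),
    )


# --------------------------------------------------------------------------
# thermal camera
# --------------------------------------------------------------------------


class ThermalConfig(_FrozenModel):
    """Low-resolution thermal camera parameters.

    The walker is rendered as a 2-D Gaussian blob of constant peak intensity
    whose pixel radius scales as ``target_angular_size_at_1m / range``, so the
    per-frame intensity sum grows as the walker approaches (occupied-pixel
    area ~ 1/range^2).  ``camera_position`` defaults to the protocol's
    thermal-camera position (1 m beyond the far turning point).
    """

    fps: float = Field(default=13.0, gt=0)
    frame_shape: tuple[int, int] = (60, 80)
    background_level: float = Field(default=20.0, ge=0)
    target_peak_intensity: float = Field(default=100.0, gt=0)
    target_angular_size_at_1m: float = Field(default=12.0, gt=0)
    camera_position: float | None = None
    noise_sd: float = Field(default=0.5, ge=0)

    @model_validator(mode="after")
    def _check_contrast(self) -> "ThermalConfig":
        if self.target_peak_intensity <= self.background_level:
            raise ValueError("target_peak_intensity must exceed background_level")
        return self


@dataclass
class ThermalFrames:
    """Sequence of 2-D intensity frames at uniform spacing 1/fps."""

    frame_times: np.ndarray
    frames: np.ndarray  # (n_frames, rows, cols)

    @property
    def fps(self) -> float:
        return 1.0 / float(self.frame_times[1] - self.frame_times[0])


def simulate_thermal_frames(
    traj: Trajectory,
    protocol: WalkProtocol,
    cfg: ThermalConfig,
    seed: int | np.random.SeedSequence | None = 0,
) -> ThermalFrames:
    """Render thermal frames of the walker seen from the end of the path."""
    cam = cfg.camera_position if cfg.camera_position is not None else protocol.camera_position
    frame_times = np.arange(0.0, traj.duration, 1.0 / cfg.fps)
    pos = np.interp(frame_times, traj.times, traj.position)
    r = np.clip(np.abs(pos - cam), 0.3, None)

    rows, cols = cfg.frame_shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    sq = (rr - r0) ** 2 + (cc - c0) ** 2  # (rows, cols)

    sigma = cfg.target_angular_size_at_1m / r  # pixels, per frame
    peak = cfg.target_peak_intensity - cfg.background_level
    blob = peak * np.exp(-sq[None, :, :] / (2.0 * sigma[:, None, None] ** 2))
    frames = cfg.background_level + blob
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + cfg.noise_sd * rng.standard_normal(frames.shape)
    return ThermalFrames(frame_times=frame_times, frames=np.clip(frames, 0.0, None))


# --------------------------------------------------------------------------
# motion-capture suit
# --------------------------------------------------------------------------


class MocapConfig(_FrozenModel):
    """Motion-capture suit head-track parameters (125 fps by default)."""

    fps: float = Field(default=125.0, gt=0)
    positional_noise_sd: float = Field(default=0.005, ge=0)
    head_height: float = Field(default=1.6, gt=0)


@dataclass
class HeadTrack:
    """3-D head coordinates per frame; x is the along-path coordinate."""

    frame_times: np.ndarray
    xyz: np.ndarray  # (n_frames, 3)

    @property
    def fps(self) -> float:
        return 1.0 / float(self.frame_times[1] - self.frame_times[0])


def simulate_mocap(
    traj: Trajectory,
    cfg: MocapConfig,
    seed: int | np.random.SeedSequence | None = 0,
) -> HeadTrack:
    """Downsample the trajectory to suit frames with additive position noise."""
    frame_times = np.arange(0.0, traj.duration, 1.0 / cfg.fps)
    x = np.interp(frame_times, traj.times, traj.position)
    xyz = np.column_stack([x, np.zeros_like(x), np.full_like(x, cfg.head_height)])
    if cfg.positional_noise_sd > 0:
        rng = np.random.default_rng(seed)
        xyz = xyz + cfg.positional_noise_sd * rng.standard_normal(xyz.shape)
    return HeadTrack(frame_times=frame_times, xyz=xyz)


# --------------------------------------------------------------------------
# pressure walkway (reference)
# --------------------------------------------------------------------------


class GaitRiteConfig(_FrozenModel):
    """Pressure-walkway parameters.

    ``active_length`` is the instrumented portion of the mat (4.27 m),
    centred within the protocol's measurement zone.  ``step_length`` is the
    footfall spacing at a 1 m/s pace and scales linearly with the walk's
    plateau speed (constant cadence).  ``light_step_probability`` corrupts a
    walk's recorded timing so its apparent speed is halved or doubled,
    exercising the outlier-omission rule.
    """

    active_length: float = Field(default=4.27, gt=0)
    sample_rate: float = Field(default=60.0, gt=0)
    spatial_sd: float = Field(default=0.0127, ge=0)
    step_length: float = Field(default=0.65, gt=0)
    foot_length: float = Field(default=0.25, gt=0)
    light_step_probability: float = Field(default=0.0, ge=0, le=1)


@dataclass
class Footfall:
    heel_position: float
    toe_position: float
    contact_time: float


@dataclass
class FootfallSequence:
    """Per-walk footfall lists; ``walks[k]`` belongs to walk index k."""

    walks: list[list[Footfall]]


def _crossing_time(t: np.ndarray, pos: np.ndarray, p: float) -> float:
    """Time at which a monotone position series crosses p (linear interp)."""
    if pos[0] > pos[-1]:
        return float(np.interp(p, pos[::-1], t[::-1]))
    return float(np.interp(p, pos, t))


def simulate_footfalls(
    traj: Trajectory,
    protocol: WalkProtocol,
    cfg: GaitRiteConfig,
    seed: int | np.random.SeedSequence | None = 0,
) -> FootfallSequence:
    """Place timed footfalls on the mat's active area for each walk.

    Footfalls are spaced by the speed-scaled step length along the active
    area; heel and toe sit half a foot length behind/ahead of the nominal
    contact point (in the direction of travel).  Contact times come from the
    trajectory crossing times, quantised to the mat's sampling grid.  The
    first footfall is stamped at heel strike and the final one at lift-off
    (the mat's timer stops when the foot leaves the mat), which makes the
    heel-to-toe distance over first-to-last time ratio exact for a
    constant-speed crossing.

    Raises
    ------
    ValueError
        If the active area does not fit inside the protocol's mat zone.
    """
    lo_zone, hi_zone = protocol.mat_zone
    margin = (protocol.mat_length - cfg.active_length) / 2.0
    if margin < -1e-9:
        raise ValueError("active area longer than the mat zone")
    lo, hi = lo_zone + margin, hi_zone - margin

    rng = np.random.default_rng(seed)
    walks: list[list[Footfall]] = []
    for w in range(protocol.n_walks):
        mask = traj.walk_index == w
        t_w, pos_w = traj.times[mask], traj.position[mask]
        direction = 1.0 if w % 2 == 0 else -1.0
        v_w = float(np.abs(traj.velocity[mask]).max())
        step = cfg.step_length * v_w  # constant cadence: spacing scales with pace
        entry = lo if direction > 0 else hi

        centers = []
        i = 0
        while True:
            p = entry + direction * (i + 0.5) * step
            if not (lo <= p <= hi):
                break
            centers.append(p)
            i += 1

        feet: list[Footfall] = []
        half_foot = cfg.foot_length / 2.0
        for j, p in enumerate(centers):
            heel = p - direction * half_foot
            toe = p + direction * half_foot
            if j == 0:
                t_c = _crossing_time(t_w, pos_w, heel)
            elif j == len(centers) - 1:
                t_c = _crossing_time(t_w, pos_w, toe)
            else:
                t_c = _crossing_time(t_w, pos_w, p)
            t_c = round(t_c * cfg.sample_rate) / cfg.sample_rate
            jitter = rng.normal(0.0, cfg.spatial_sd) if cfg.spatial_sd > 0 else 0.0
            feet.append(Footfall(heel + jitter, toe + jitter, t_c))

        if feet and rng.random() < cfg.light_step_probability:
            # a light step mis-records the walk: apparent speed halved/doubled
            factor = rng.choice([0.5, 2.0])
            t0 = feet[0].contact_time
            for f in feet:
                f.contact_time = t0 + (f.contact_time - t0) / factor
        walks.append(feet)
    return FootfallSequence(walks=walks)
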