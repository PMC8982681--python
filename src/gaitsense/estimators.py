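"""Per-sensor gait-speed estimation procedures.

Each estimator turns one sensor's observation into a :class:`SpeedEstimate`
with per-walk speeds and a trial average, in one of two modes:

* ``primary`` — speed over the full walk, including the acceleration,
  deceleration and turnaround phases the walkway reference never sees;
* ``secondary`` — speed over only the mat-equivalent middle interval
  (constant-speed portion), mirroring what the walkway measures.

The procedures:

* **CW radar** — short-time Fourier transform of the complex baseband signal;
  per time column the peak-power frequency bin is taken (power-gated against
  the column median), the retained peak frequencies are averaged into a
  Doppler shift Δf, and speed follows from Δv = c·Δf / (doppler_factor·f0).
  ``doppler_factor=2`` is the monostatic two-way physics; ``1`` reproduces the
  one-way form of the conversion as sometimes printed.
* **UWB radar** — background (clutter) subtraction, per-pulse peak-bin range
  track, then range excursion / duration (primary) or a linear fit of range
  vs time over the mat interval (secondary).
* **Thermal camera** — the per-frame pixel-intensity sum peaks when the
  walker is nearest the camera; local maxima/minima mark the turnaround
  points.  Primary: known key-location separation / extremum spacing.
  Secondary: per round trip, maximum-to-maximum time minus the off-mat time,
  with speed = 2·mat_length / remaining time.
* **Motion suit** — turnaround extrema of the along-path head coordinate;
  displacement between consecutive extrema over elapsed frames (primary) or
  displacement across a 250-frame window centred on each walk (secondary).
* **Walkway reference** — heel-of-first to toe-of-last distance over
  first-to-last contact time per walk, with the outlier rule that omits any
  walk whose speed is at most half or at least double the mean of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.signal import find_peaks, get_window

from .sensors import (
    CWRadarConfig,
    CWSignal,
    FootfallSequence,
    HeadTrack,
    RangeProfileStack,
    ThermalConfig,
    ThermalFrames,
)
from .walker import WalkProtocol

__all__ = [
    "STFTConfig",
    "Spectrogram",
    "DopplerEstimate",
    "SpeedEstimate",
    "ReferenceSpeed",
    "RangeTrack",
    "stft_spectrogram",
    "estimate_speed_cw",
    "uwb_range_track",
    "estimate_speed_uwb",
    "thermal_intensity_series",
    "find_intensity_extrema",
    "estimate_speed_thermal",
    "thermal_speed_resolution",
    "estimate_speed_suit",
    "gaitrite_speed",
]


class STFTConfig(BaseModel):
    """Short-time Fourier transform parameters (window length and hop in s)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    window: str = "hann"
    window_length: float = Field(default=0.5, gt=0)
    hop: float = Field(default=0.05, gt=0)
    fft_size: int = Field(default=4096, gt=0)


@dataclass
class Spectrogram:
    """Time-frequency power map; frequencies are signed (complex input)."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # (n_freqs, n_times)


@dataclass
class DopplerEstimate:
    """Per-walk averaged Doppler shift and its speed conversion."""

    delta_f: list[float]  # Hz, signed; NaN where unusable
    delta_v: list[float]  # m/s, signed


@dataclass
class SpeedEstimate:
    """Per-walk unsigned speeds plus trial summary for one sensor/mode."""

    sensor: str
    mode: str
    per_walk_speed: list[float]  # NaN marks an unusable walk/segment
    trial_mean: float
    trial_sd: float
    n_walks_used: int


@dataclass
class ReferenceSpeed(SpeedEstimate):
    """Walkway reference estimate with the indices of omitted walks."""

    omitted_walks: list[int] = field(default_factory=list)


def _summarize(sensor: str, mode: str, speeds: list[float]) -> SpeedEstimate:
    arr = np.asarray(speeds, dtype=float)
    used = arr[np.isfinite(arr)]
    mean = float(used.mean()) if used.size else float("nan")
    sd = float(used.std(ddof=1)) if used.size > 1 else 0.0
    return SpeedEstimate(
        sensor=sensor,
        mode=mode,
        per_walk_speed=[float(s) for s in arr],
        trial_mean=mean,
        trial_sd=sd,
        n_walks_used=int(used.size),
    )


# --------------------------------------------------------------------------
# CW radar: spectrogram + Doppler conversion
# --------------------------------------------------------------------------


def stft_spectrogram(sig: CWSignal, cfg: STFTConfig) -> Spectrogram:
    """Spectrogram S(t, f) = |sum_n w(n) x(t - n) e^{-j 2 pi f n}|^2.

    Columns are windowed frames hopped along the signal; each frame is
    tapered, zero-padded to ``fft_size`` and transformed.  Signed frequencies
    are preserved (the input is complex baseband), ordered ascending.

    Raises
    ------
    ValueError
        If the signal is shorter than one window or ``fft_size`` is smaller
        than the window.
    """
    fs = sig.sample_rate
    n_win = int(round(cfg.window_length * fs))
    n_hop = int(round(cfg.hop * fs))
    if n_hop < 1 or n_hop > n_win:
        raise ValueError("hop must be positive and no longer than the window")
    if sig.samples.size < n_win:
        raise ValueError("signal shorter than one analysis window")
    if cfg.fft_size < n_win:
        raise ValueError("fft_size must be at least the window length in samples")

    w = get_window(cfg.window, n_win, fftbins=True)
    starts = np.arange(0, sig.samples.size - n_win + 1, n_hop)
    frames = np.lib.stride_tricks.sliding_window_view(sig.samples, n_win)[starts]
    spec = np.fft.fft(frames * w, n=cfg.fft_size, axis=1)
    power = np.fft.fftshift(np.abs(spec) ** 2, axes=1).T
    freqs = np.fft.fftshift(np.fft.fftfreq(cfg.fft_size, d=1.0 / fs))
    times = sig.start_time + (starts + n_win / 2.0) / fs
    return Spectrogram(times=times, freqs=freqs, power=power)


def estimate_speed_cw(
    spec: Spectrogram,
    cw_cfg: CWRadarConfig,
    walk_windows: list[tuple[float, float] | None],
    mode: str = "primary",
    doppler_factor: float = 2.0,
    power_gate_db: float = 6.0,
    window_length: float | None = None,
) -> tuple[DopplerEstimate, SpeedEstimate]:
    """Extract per-walk speeds from the spectrogram's peak-power ridge.

    For each walk window, columns whose centre lies fully inside the window
    are inspected; each contributes the frequency of its peak-power bin,
    retained only if the peak exceeds the column's median power by
    ``power_gate_db`` (gating out noise-floor columns).  The mean retained
    frequency is the walk's Doppler shift Δf, converted to speed via
    Δv = c·Δf / (doppler_factor·f0).  Walks with no retained column are
    flagged unusable (NaN).

    ``walk_windows`` should already reflect the analysis mode (full-walk
    spans for primary, constant-speed in-field-of-view sub-windows for
    secondary); ``window_length`` (s) shrinks each window by half an STFT
    window on each side so no column straddles the boundary.
    """
    half = (window_length or 0.0) / 2.0
    delta_f: list[float] = []
    speeds: list[float] = []
    for win in walk_windows:
        if win is None:
            delta_f.append(float("nan"))
            speeds.append(float("nan"))
            continue
        t0, t1 = win[0] + half, win[1] - half
        cols = np.where((spec.times >= t0) & (spec.times < t1))[0]
        peaks: list[float] = []
        for c in cols:
            col = spec.power[:, c]
            i = int(np.argmax(col))
            med = float(np.median(col))
            if med <= 0.0 or 10.0 * math.log10(col[i] / med) >= power_gate_db:
                peaks.append(float(spec.freqs[i]))
        if not peaks:
            delta_f.append(float("nan"))
            speeds.append(float("nan"))
            continue
        df = float(np.mean(peaks))
        delta_f.append(df)
        speeds.append(abs(cw_cfg.c * df / (doppler_factor * cw_cfg.f0)))
    dv = [cw_cfg.c * f / (doppler_factor * cw_cfg.f0) for f in delta_f]
    return DopplerEstimate(delta_f=delta_f, delta_v=dv), _summarize("cw_radar", mode, speeds)


# --------------------------------------------------------------------------
# UWB radar: clutter removal + range track
# --------------------------------------------------------------------------


@dataclass
class RangeTrack:
    """Per-pulse target range after background subtraction."""

    times: np.ndarray
    range_m: np.ndarray
    valid: np.ndarray  # boolean; False where the residual peak fell below gate


def uwb_range_track(stack: RangeProfileStack, threshold: float = 0.01) -> RangeTrack:
    """Track the target range as the peak residual bin of each pulse.

    The static background (clutter) capture is subtracted from every pulse,
    negative residuals floored at zero; the bin of maximum residual gives the
    range, marked missing when that maximum falls below ``threshold``.

    Raises
    ------
    ValueError
        If no pulse yields a residual above the threshold (all-missing track).
    """
    residual = np.clip(stack.amplitudes - stack.background[None, :], 0.0, None)
    idx = np.argmax(residual, axis=1)
    peak = residual[np.arange(residual.shape[0]), idx]
    valid = peak > threshold
    if not valid.any():
        raise ValueError("all-missing range track: no residual above threshold")
    return RangeTrack(times=stack.pulse_times, range_m=stack.bins[idx], valid=valid)


def estimate_speed_uwb(
    track: RangeTrack,
    walk_windows: list[tuple[float, float] | None],
    mode: str = "primary",
) -> SpeedEstimate:
    """Per-walk speed from the range-vs-time track.

    Primary: range excursion over the walk divided by the walk duration.
    Secondary: absolute slope of a least-squares line fitted to range vs time
    restricted to the mat-equivalent middle section.  Walks with fewer than
    three valid track points are flagged unusable.
    """
    speeds: list[float] = []
    for win in walk_windows:
        if win is None:
            speeds.append(float("nan"))
            continue
        t0, t1 = win
        m = track.valid & (track.times >= t0) & (track.times < t1)
        if m.sum() < 3:
            speeds.append(float("nan"))
            continue
        if mode == "primary":
            speeds.append(float(track.range_m[m].max() - track.range_m[m].min()) / (t1 - t0))
        elif mode == "secondary":
            slope = np.polyfit(track.times[m], track.range_m[m], 1)[0]
            speeds.append(abs(float(slope)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return _summarize("uwb_radar", mode, speeds)


# --------------------------------------------------------------------------
# thermal camera: intensity-sum extrema
# --------------------------------------------------------------------------


def thermal_intensity_series(frames: ThermalFrames) -> np.ndarray:
    """Per-frame sum of pixel intensities (one scalar per frame)."""
    return frames.frames.reshape(frames.frames.shape[0], -1).sum(axis=1)


def _refine_to_plateau_midpoint(
    series: np.ndarray, peaks: np.ndarray, prominences: np.ndarray, rel_height: float
) -> np.ndarray:
    """Move each peak to the midpoint of its near-peak plateau.

    The walker dwells at each turnaround, so the intensity extremum is a flat
    plateau and the sample-level argmax lands anywhere on it under noise.
    The region within ``rel_height`` of the peak's own prominence is symmetric
    about the dwell, so its midpoint is a stable, jitter-free timestamp.
    """
    refined = []
    for p, prom in zip(peaks, prominences):
        thr = series[p] - rel_height * prom
        lo = p
        while lo > 0 and series[lo - 1] >= thr:
            lo -= 1
        hi = p
        while hi < series.size - 1 and series[hi + 1] >= thr:
            hi += 1
        refined.append((lo + hi) // 2)
    return np.asarray(refined, dtype=int)


def find_intensity_extrema(
    series: np.ndarray,
    fps: float,
    prominence_frac: float = 0.1,
    min_separation_s: float | None = None,
    rel_height: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima of the intensity-sum series.

    Prominence is ``prominence_frac`` of the series' dynamic range and
    ``min_separation_s`` sets the minimum spacing between extrema of the same
    kind; each extremum is then refined to the midpoint of its near-peak
    plateau (see :func:`_refine_to_plateau_midpoint`).  The end of the
    recording closes the final trough (the walker has returned to the far
    point and the trial ends there), so a terminal minimum is counted; the
    flat lead-in before walking starts is not.
    """
    series = np.asarray(series, dtype=float)
    prom = prominence_frac * (series.max() - series.min())
    dist = max(1, int(round((min_separation_s or 1.0 / fps) * fps)))
    maxima, props = find_peaks(series, prominence=prom, distance=dist)
    maxima = _refine_to_plateau_midpoint(series, maxima, props["prominences"], rel_height)
    inv = series.max() - series
    inv_closed = np.append(inv, 0.0)  # recording end closes the last trough
    minima, props = find_peaks(inv_closed, prominence=prom, distance=dist)
    keep = minima < series.size
    minima = _refine_to_plateau_midpoint(
        inv, minima[keep], props["prominences"][keep], rel_height
    )
    return maxima, minima


def thermal_speed_resolution(speed_mps: float, fps: float) -> float:
    """Smallest resolvable speed step: distance covered per frame interval."""
    return speed_mps / fps


def estimate_speed_thermal(
    series: np.ndarray,
    cfg: ThermalConfig,
    protocol: WalkProtocol,
    mode: str = "primary",
    off_mat_time_rt: float = 4.0,
    key_distance: float | None = None,
    prominence_frac: float = 0.1,
    min_separation_s: float | None = None,
) -> SpeedEstimate:
    """Gait speed from the thermal intensity-sum time series.

    Primary: consecutive extrema (alternating nearest/farthest points) are
    ``key_distance`` apart — the walker's full excursion, defaulting to the
    protocol's path length — so each adjacent pair yields
    speed = key_distance / (frame spacing / fps).

    Secondary: consecutive maxima are one round trip apart.  Subtracting the
    time spent off the measurement zone (``off_mat_time_rt`` seconds per round
    trip; the device's classic assumption of ~2 s per turnaround-adjacent
    episode gives 4 s, while :func:`gaitsense.walker.off_mat_time_per_round_trip`
    supplies the protocol-derived value) leaves the on-mat time, and
    speed = 2 * mat_length / on-mat time.

    Raises
    ------
    ValueError
        If the number of detected maxima differs from the protocol's number
        of round trips (the error names the count found).
    """
    n_rt = protocol.n_round_trips
    if min_separation_s is None:
        # half the expected half-lap duration, from the series span
        min_separation_s = 0.5 * (len(series) / cfg.fps) / (2 * n_rt)
    maxima, minima = find_intensity_extrema(
        series, cfg.fps, prominence_frac=prominence_frac, min_separation_s=min_separation_s
    )
    if maxima.size != n_rt:
        raise ValueError(f"expected {n_rt} intensity maxima, found {maxima.size}")

    speeds: list[float] = []
    if mode == "primary":
        dist = protocol.path_length if key_distance is None else key_distance
        extrema = np.sort(np.concatenate([maxima, minima]))
        for a, b in zip(extrema[:-1], extrema[1:]):
            speeds.append(dist / ((b - a) / cfg.fps))
    elif mode == "secondary":
        for a, b in zip(maxima[:-1], maxima[1:]):
            on_mat = (b - a) / cfg.fps - off_mat_time_rt
            speeds.append(2.0 * protocol.mat_length / on_mat if on_mat > 0 else float("nan"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _summarize("thermal", mode, speeds)


# --------------------------------------------------------------------------
# motion-capture suit: turnaround extrema of the head track
# --------------------------------------------------------------------------


def estimate_speed_suit(
    track: HeadTrack,
    mode: str = "primary",
    n_walks: int = 6,
    window_frames: int = 250,
    prominence_frac: float = 0.1,
) -> SpeedEstimate:
    """Gait speed from the along-path head coordinate.

    Turnaround points are the interior extrema of x plus the first and last
    frames (the trial starts and ends at rest at the start point), giving
    ``n_walks + 1`` turning points.  Primary: |displacement| between
    consecutive turning points over the elapsed frames.  Secondary: a
    ``window_frames``-frame window centred midway between turning points,
    speed = |displacement across the window| / (window duration).

    Raises
    ------
    ValueError
        If fewer turning points than walks are found.
    """
    x = track.xyz[:, 0]
    fps = track.fps
    span = float(x.max() - x.min())
    prom = prominence_frac * span
    dist = max(1, int(round(0.5 * (x.size / n_walks))))
    hi, _ = find_peaks(x, prominence=prom, distance=dist)
    lo, _ = find_peaks(-x, prominence=prom, distance=dist)
    turning = np.unique(np.concatenate([[0], hi, lo, [x.size - 1]]))
    if turning.size < n_walks + 1:
        raise ValueError(
            f"found {turning.size - 1} walk segments, expected at least {n_walks}"
        )

    speeds: list[float] = []
    for a, b in zip(turning[:-1], turning[1:]):
        if mode == "primary":
            speeds.append(abs(x[b] - x[a]) / ((b - a) / fps))
        elif mode == "secondary":
            c = (a + b) // 2
            half = window_frames // 2
            i0, i1 = max(a, c - half), min(b, c + half)
            if i1 <= i0:
                speeds.append(float("nan"))
                continue
            speeds.append(abs(x[i1] - x[i0]) / ((i1 - i0) / fps))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return _summarize("suit", mode, speeds)


# --------------------------------------------------------------------------
# pressure walkway reference
# --------------------------------------------------------------------------


def _walk_speed(feet: list) -> float:
    if len(feet) < 2:
        return float("nan")
    first, last = feet[0], feet[-1]
    dt = last.contact_time - first.contact_time
    if dt <= 0:
        return float("nan")
    return abs(last.toe_position - first.heel_position) / dt


def gaitrite_speed(footfalls: FootfallSequence) -> ReferenceSpeed:
    """Reference speed from the walkway footfalls, with outlier omission.

    Per walk, speed is the heel-of-first to toe-of-last distance over the
    first-to-last contact time.  Any walk whose speed is at most half or at
    least double the mean of the remaining walks is omitted and the trial
    average uses the rest; the rule is iterated to a fixed point so that
    re-applying it to the retained walks omits nothing further.  Walks with
    fewer than two footfalls are unusable and treated as omitted.
    """
    raw = [_walk_speed(feet) for feet in footfalls.walks]
    speeds = np.asarray(raw, dtype=float)
    keep = np.isfinite(speeds)
    changed = True
    while changed and keep.sum() > 1:
        changed = False
        for i in np.where(keep)[0]:
            others = speeds[keep & (np.arange(speeds.size) != i)]
            if others.size == 0:
                continue
            m = others.mean()
            if speeds[i] <= 0.5 * m or speeds[i] >= 2.0 * m:
                keep[i] = False
                changed = True
                break  # restart with the reduced set
    used = speeds[keep]
    omitted = [int(i) for i in np.where(~keep)[0]]
    per_walk = [float(s) if keep[i] else float("nan") for i, s in enumerate(speeds)]
    return ReferenceSpeed(
        sensor="gaitrite",
        mode="reference",
        per_walk_speed=per_walk,
        trial_mean=float(used.mean()) if used.size else float("nan"),
        trial_sd=float(used.std(ddof=1)) if used.size > 1 else 0.0,
        n_walks_used=int(used.size),
        omitted_walks=omitted,
    )
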