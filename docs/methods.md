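# Methods

## Problem and scope

`gaitsense` is a simulation testbed for privacy-preserving gait-speed
measurement. It reproduces, on fully synthetic data, a comparative protocol in
which four ambient sensing modalities — a 24-GHz continuous-wave (CW)
micro-Doppler radar, a pulsed ultra-wideband (UWB) radar, a low-resolution
thermal camera, and a motion-capture suit — each estimate a walker's speed,
and every estimate is compared against a pressure-sensitive walkway
(GAITRite-style) reference. Because the walkway only observes the steady
middle of each walk while the other sensors see the whole walk, every
comparison is run twice: a **primary** analysis over the full walk (including
acceleration, deceleration and turnarounds) and a **secondary**,
mat-equivalent analysis cropped to the interval the walkway actually covers.
The scientific claim the testbed exercises is parameter recovery: a correctly
implemented estimator, given the mat-equivalent window, should recover the
walker's plateau speed; given the full walk it should be biased low.

## Walker model

The walk protocol is a straight path of length `path_length` (default 7 m)
whose middle `mat_length` (default 5 m, starting `mat_start_offset` = 1 m
from the start point X1) is the measurement zone. A trial is
`n_round_trips` = 3 there-and-back round trips, i.e. six walks, separated by
stationary turnaround dwells of `turnaround_dwell` = 2 s. Speed follows a
trapezoidal profile: constant acceleration `accel` from rest, a plateau at
`steady_speed`, constant deceleration to rest at the far end. No published
acceleration model exists for this protocol, so `accel` defaults to
0.5 m/s², which brings an adult to 1 m/s in 2 s over the first metre — the
ramps then sit entirely on the off-mat buffer for paces up to 1 m/s.
Kinematics are evaluated in closed form on a uniform master grid (default
1000 Hz), so there is no integration drift; all sensor models downsample or
interpolate from this grid.

Positions are metres from X1; velocity is the signed derivative of position
(positive = away from the start). The radars sit 1 m behind X1
(`sensor_positions["radar"] = -1`), so target range is position + 1 m; with
the 24-GHz radar's 3.5 m usable field of view this covers roughly the first
2.5 m of the mat zone, matching the equipment geometry the protocol
describes. The thermal camera sits 1 m beyond the far turning point.

Ground truth per trial is the set of closed-form mat-crossing intervals and
their speeds; the trial mean of those crossing speeds is what the walkway
reference measures and is the recovery target for the secondary analyses.

## Sensor forward models

**CW radar.** Baseband sample `A(r)·exp(-j·4π r/λ)` (two-way phase;
configurable to one-way), amplitude `r^-k` with `k = 2` chosen for baseband
envelope simplicity rather than the full radar-equation `r^-4`, an
exponential attenuation (3 nepers/m) beyond the 3.5 m field of view, and
additive complex white noise (relative SD 0.02). An approaching walker
produces a positive Doppler frequency `2 v f0 / c` (≈ 96 Hz at 0.6 m/s,
160 Hz at 1 m/s), safely below the 500 Hz Nyquist of the default 1 kHz
sampling.

**UWB radar.** 100 pulses/s over 200 bins of 0.05 m (10 m unambiguous
range). Each pulse holds a Gaussian echo of SD `echo_width_bins/2` bins
centred on the target range, peak `r^-2` (unit at 1 m), on top of a smooth
static clutter profile (amplitude 0.02) plus white noise (SD 0.002); a
target-free background capture (clutter + independent noise) accompanies the
stack. Targets beyond 10 m simply contribute no echo.

**Thermal camera.** 13 fps frames of 60×80 pixels. The walker is a 2-D
Gaussian blob of constant peak intensity (100 against a background of 20)
whose pixel radius is `12 px / range`, so occupied area — and hence the
per-frame intensity sum — grows as `1/r²` on approach. Per-pixel noise SD
0.5. A full trial at 1 m/s yields roughly a thousand frames, the order of
magnitude a real capture produces.

**Motion suit.** The head track is the trajectory interpolated at 125 fps
with isotropic Gaussian positional noise (SD 5 mm) in x, y, z.

**Walkway.** Footfalls are kinematic stamps (not pressure images): contact
points spaced by a speed-scaled step length (0.65 m at 1 m/s, constant
cadence) along the 4.27 m active area centred in the 5 m mat zone, heel and
toe half a `foot_length` (0.25 m) behind/ahead, positions jittered with the
device's ±1.27 cm spatial accuracy and times quantised to its 60 Hz grid.
The first footfall is stamped at heel strike and the last at lift-off — the
device's timer stops when the foot leaves the mat — which makes the
heel-of-first-to-toe-of-last over first-to-last-time ratio exact for a
constant-speed crossing. An optional "light step" corruption
(`light_step_probability`) halves or doubles a walk's apparent speed to
exercise the reference's outlier rule.

Each trial's master seed is split deterministically (`SeedSequence.spawn`)
into independent per-sensor streams; every simulator is bit-reproducible
given (trajectory, config, seed).

## Estimators

**CW micro-Doppler.** The spectrogram is
`S(t,f) = |Σ_n w(n) x(t-n) e^(-j2πfn)|²` with a 0.5 s Hann window, 50 ms
hop, and 4096-point zero-padded FFT (signed frequencies kept; the input is
complex). Per walk window, each column contributes its peak-power frequency
bin, retained when the peak exceeds the column median by 6 dB; the mean
retained frequency is the walk's Doppler shift Δf, and speed is
`|c·Δf / (doppler_factor · f0)|`. `doppler_factor = 2` (default) is the
monostatic two-way physics; `1` reproduces the one-way form of the
conversion formula as it is sometimes printed. Secondary windows are the
constant-speed samples inside both the mat zone and the field of view.
The speed quantum set by the window is `c/(2 f0 W)` ≈ 0.0125 m/s; FFT
padding locates the peak well inside that. Note the gate is deliberately
permissive: the maximum of ~4096 exponential-power noise bins sits ~11 dB
above their median, so pure-noise columns (walker far out of view) can pass
and pull the full-walk primary estimate further below the plateau speed;
the secondary windows contain no such columns.

**UWB range track.** Background subtraction (floored at zero), per-pulse
argmax bin gated at an absolute residual threshold (0.01 of the 1 m echo
amplitude — above the clutter-residual noise floor yet below the weakest
in-range echo). Primary: range excursion over walk duration. Secondary:
absolute slope of a least-squares line over the mat interval. Walks with
fewer than three valid points are flagged unusable.

**Thermal intensity extrema.** The per-frame intensity sum peaks at closest
approach and bottoms at the far point. Extrema are found with
`scipy.signal.find_peaks` (prominence 10 % of the dynamic range, minimum
separation half the expected half-lap), then refined to the midpoint of the
plateau within 5 % of the peak's prominence: the walker dwells at each
turnaround, so the extremum is a flat plateau and the raw argmax lands
anywhere on it under noise, whereas the plateau is symmetric about the dwell
and its midpoint is stable. The end of the recording closes the final
trough (the last return completes the trial), so a three-round-trip trial
yields exactly three maxima and three minima; a mismatched maxima count is
an error naming the count found. Primary: consecutive extrema are one full
path excursion apart, so speed = `path_length / spacing`. Secondary:
consecutive maxima are one round trip apart; subtracting the off-mat time
per round trip leaves the on-mat time and speed = `2·mat_length / on-mat
time`. The method's classic assumption is ~2 s per turnaround-adjacent
off-mat episode (4 s per round trip), which is accurate only when
turnarounds are instantaneous; the pipeline instead supplies the off-mat
time computed from the protocol geometry at the pace *target* speed (public
protocol knowledge — not the participant's realized speed, which remains
unknown to the estimator). The residual error from target-vs-realized speed
mismatch is below ~2.5 % at the default pace spreads. The camera's frame
interval bounds precision: at 15 fps and 1 m/s the speed quantum is
1/15 m ≈ 0.07 m/s.

**Motion suit.** Turnaround points are the interior extrema of the
along-path head coordinate (prominence 10 % of the excursion) plus the first
and last frames (the trial starts and ends at rest). Primary:
|displacement| between consecutive turning points over the elapsed frames —
which necessarily includes dwell time, biasing low. Secondary: a 250-frame
(2 s) window centred midway between turning points, which falls inside the
plateau; speed = |displacement across the window| / 2 s.

**Walkway reference.** Per walk, speed = |toe of last − heel of first| /
(last − first contact time). Any walk whose speed is ≤ half or ≥ double the
mean of the remaining walks is omitted (a "light step" artefact) and the
trial mean uses the rest. The rule is iterated to a fixed point, so
re-applying it to the retained walks omits nothing further; in the intended
single-outlier regime one pass suffices and the trial uses 5 of 6 walks.

## Experiment driver and error summaries

`run_experiment` simulates `n_participants` (default 10) at two pace targets
(normal 1.0 m/s, slow 0.6 m/s), drawing each participant's steady speed from
a Gaussian around the target (SD 0.12 / 0.08 m/s, truncated at ±2 SD —
matching the between-participant spread such cohorts show), then runs all
sensors and both modes. Errors vs the walkway reference are summarised per
(sensor, pace, mode) as mean ± sample SD (ddof = 1) of the unsigned percent
deviation `100·|est − ref|/ref` and of the absolute deviation in m/s.
Missing cells (estimator failures) are excluded from means, not imputed.
A single-trial cell reports SD = 0 with `n_trials` flagging the degenerate
sample.

## Numerical choices and conventions

- Intervals are half-open `[start, stop)`; STFT columns are timestamped at
  the window centre, and windows are shrunk by half an STFT window per side
  so no column straddles a boundary.
- Argmax ties break toward the earlier index (NumPy convention); flat-peak
  extrema use the plateau midpoint.
- Estimators return unsigned speeds; direction is metadata (the Doppler
  estimate keeps the signed Δf).
- All seeds derive from one master seed via `numpy.random.SeedSequence`.
- Serialisation: trials to HDF5 (one group per trial, config hash and seed
  as attributes), tables to CSV with a provenance comment line.

## What the generator does and does not emulate

The simulator captures the geometry, timing, sampling rates and first-order
noise of each modality, which is what the estimators' windowing, gating and
timing corrections respond to. It does **not** model per-limb micro-Doppler
signatures, multipath or wall effects, antenna patterns, thermal silhouettes
or ambient thermal drift, suit calibration errors, or inter-device clock
skew (all sensors share the simulation clock; real deployments do not).
Passing recovery tests here therefore shows the estimation chains are
implemented correctly and respond to cropping as expected — not that the
error magnitudes transfer to real hardware, where the listed effects
dominated the reported discrepancies.

## Known limitations

- The secondary CW windows are derived from the ground-truth trajectory
  rather than segmented blindly from the spectrogram; the corresponding real
  procedure selected the constant-speed marks manually.
- The thermal secondary correction uses protocol timing at the pace target;
  a field deployment without a protocol would need the fixed ~4 s assumption
  and inherit its speed-dependent bias (slow paces underestimated).
- The walkway model stamps idealised footfalls; pressure-image artefacts
  other than the light-step corruption are not represented.

## Problem sizes used in checks

The packaged checks run ten noise-free recovery trials (five speeds around
each pace target), a ten-participant noisy experiment for the
cropping-effect comparison (the acceptance script) and a five-participant
one in the test suite, twenty seeds for the thermal extremum counts, and
twenty random signals for the STFT-vs-DFT oracle comparison.
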