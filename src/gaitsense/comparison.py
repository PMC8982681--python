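"""Multi-participant synthetic experiments and error summaries.

Runs the full simulate → estimate pipeline for N participants at two pace
targets (normal ~1.0 m/s, slow ~0.6 m/s), compares every sensor's trial-mean
speed against the walkway reference, and summarises percent and absolute
deviations (mean ± sample SD) per (sensor, pace, mode) — the same layout as a
two-block error table with % and m/s entries.

The ``primary`` mode analyses the whole walk (ramps, dwells and all) while
``secondary`` crops to the mat-equivalent interval; because the reference
only ever sees the steady middle of the walk, the secondary analysis is the
like-for-like comparison and its errors are systematically smaller whenever
the primary window spans ramps or dwells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from . import sensors as sens
from . import walker
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrialData",
    "TrialResult",
    "percent_error",
    "summarize",
    "simulate_trial",
    "estimate_trial",
    "run_experiment",
]

SENSOR_NAMES = ("cw_radar", "uwb_radar", "thermal", "suit")


@dataclass
class TrialData:
    """All simulated observations for one participant/pace trial."""

    participant_id: int
    pace_label: str
    steady_speed: float
    protocol: walker.WalkProtocol
    profile: walker.SpeedProfile
    trajectory: walker.Trajectory
    ground_truth: walker.GroundTruth
    cw: sens.CWSignal
    uwb: sens.RangeProfileStack
    thermal: sens.ThermalFrames
    mocap: sens.HeadTrack
    footfalls: sens.FootfallSequence


@dataclass
class TrialResult:
    """Reference and per-sensor estimates for one trial."""

    participant_id: int
    pace_label: str
    steady_speed: float
    ground_truth_mean: float
    reference: est.ReferenceSpeed
    estimates: dict[tuple[str, str], est.SpeedEstimate] = field(default_factory=dict)


def percent_error(estimate_mean: float, reference_mean: float) -> float:
    """Unsigned percent deviation, 100 * |estimate - reference| / reference.

    Raises
    ------
    ValueError
        If the reference is not strictly positive.
    """
    if not reference_mean > 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * abs(estimate_mean - reference_mean) / reference_mean


def simulate_trial(
    config: RunConfig,
    profile: walker.SpeedProfile,
    participant_id: int,
    seed: int | np.random.SeedSequence,
) -> TrialData:
    """Simulate one trial: trajectory plus all five sensor observations.

    One master seed per trial is split deterministically into independent
    per-sensor streams.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cw, s_uwb, s_th, s_mc, s_gr = ss.spawn(5)
    protocol = config.protocol
    traj, gt = walker.simulate_trajectory(protocol, profile, config.master_sample_rate)
    return TrialData(
        participant_id=participant_id,
        pace_label=profile.pace_label,
        steady_speed=profile.steady_speed,
        protocol=protocol,
        profile=profile,
        trajectory=traj,
        ground_truth=gt,
        cw=sens.simulate_cw_signal(traj, protocol, config.cw, s_cw),
        uwb=sens.simulate_uwb_stack(traj, protocol, config.uwb, s_uwb),
        thermal=sens.simulate_thermal_frames(traj, protocol, config.thermal, s_th),
        mocap=sens.simulate_mocap(traj, config.mocap, s_mc),
        footfalls=sens.simulate_footfalls(traj, protocol, config.gaitrite, s_gr),
    )


def estimate_trial(
    data: TrialData,
    config: RunConfig,
    pace_target_speed: float,
    modes: tuple[str, ...] = ("primary", "secondary"),
) -> TrialResult:
    """Run every estimator (both modes) plus the reference on one trial.

    The thermal secondary analysis needs the off-mat time per round trip;
    it is derived from the protocol geometry at the pace *target* speed
    (public protocol knowledge), not the participant's realized speed.
    An estimator failure leaves that cell missing and the run continues.
    """
    protocol, traj, gt = data.protocol, data.trajectory, data.ground_truth
    reference = est.gaitrite_speed(data.footfalls)
    result = TrialResult(
        participant_id=data.participant_id,
        pace_label=data.pace_label,
        steady_speed=data.steady_speed,
        ground_truth_mean=gt.trial_mean_speed,
        reference=reference,
    )

    spec = est.stft_spectrogram(data.cw, config.stft)
    track = est.uwb_range_track(data.uwb, threshold=config.uwb_track_threshold)
    series = est.thermal_intensity_series(data.thermal)
    target_profile = walker.build_speed_profile(
        data.pace_label, pace_target_speed, config.profile_accel, protocol.path_length
    )
    off_mat = walker.off_mat_time_per_round_trip(protocol, target_profile)

    for mode in modes:
        cw_windows = walker.cw_observation_windows(
            traj, protocol, config.cw.fov_range, mode=mode
        )
        uwb_windows = (
            walker.walk_spans(traj)
            if mode == "primary"
            else walker.mat_segment_intervals(traj, protocol)
        )
        runners = {
            "cw_radar": lambda m=mode, w=cw_windows: est.estimate_speed_cw(
                spec,
                config.cw,
                w,
                mode=m,
                doppler_factor=config.doppler_factor,
                window_length=config.stft.window_length,
            )[1],
            "uwb_radar": lambda m=mode, w=uwb_windows: est.estimate_speed_uwb(
                track, w, mode=m
            ),
            "thermal": lambda m=mode: est.estimate_speed_thermal(
                series, config.thermal, protocol, mode=m, off_mat_time_rt=off_mat
            ),
            "suit": lambda m=mode: est.estimate_speed_suit(
                data.mocap, mode=m, n_walks=protocol.n_walks
            ),
        }
        for name, run in runners.items():
            try:
                result.estimates[(name, mode)] = run()
            except ValueError as exc:  # estimator failure: record missing, continue
                logger.warning(
                    "trial p%d/%s: %s %s failed: %s",
                    data.participant_id,
                    data.pace_label,
                    name,
                    mode,
                    exc,
                )
    return result


def summarize(results: list[TrialResult]) -> pd.DataFrame:
    """Mean ± sample SD of percent and absolute deviations vs the reference.

    One row per (sensor, pace, mode) present in the results; trials whose
    estimate or reference is missing are excluded from that cell (logged).
    With a single trial the SD is reported as 0 and ``n_trials`` flags the
    degenerate sample size.
    """
    rows = []
    cells: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for r in results:
        ref = r.reference.trial_mean
        for (sensor, mode), e in r.estimates.items():
            if not (np.isfinite(e.trial_mean) and np.isfinite(ref) and ref > 0):
                logger.warning(
                    "excluding trial p%d/%s from %s/%s summary (missing value)",
                    r.participant_id,
                    r.pace_label,
                    sensor,
                    mode,
                )
                continue
            cells.setdefault((sensor, r.pace_label, mode), []).append(
                (percent_error(e.trial_mean, ref), abs(e.trial_mean - ref))
            )
    for (sensor, pace, mode), vals in sorted(cells.items()):
        pct = np.array([v[0] for v in vals])
        abs_err = np.array([v[1] for v in vals])
        rows.append(
            {
                "sensor": sensor,
                "pace": pace,
                "mode": mode,
                "mean_pct_error": pct.mean(),
                "sd_pct_error": pct.std(ddof=1) if pct.size > 1 else 0.0,
                "mean_abs_error_mps": abs_err.mean(),
                "sd_abs_error_mps": abs_err.std(ddof=1) if abs_err.size > 1 else 0.0,
                "n_trials": len(vals),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sensor",
            "pace",
            "mode",
            "mean_pct_error",
            "sd_pct_error",
            "mean_abs_error_mps",
            "sd_abs_error_mps",
            "n_trials",
        ],
    )


def _draw_speed(
    rng: np.random.Generator, target: float, sd: float, max_sigma: float = 2.0
) -> float:
    """Gaussian draw around the pace target, truncated at ±max_sigma SD."""
    while True:
        v = rng.normal(target, sd)
        if abs(v - target) <= max_sigma * sd:
            return float(v)


def run_experiment(
    config: RunConfig,
) -> tuple[list[TrialResult], pd.DataFrame, pd.DataFrame]:
    """Simulate and analyse the whole multi-participant experiment.

    Per-participant steady speeds are drawn around each pace target;
    everything downstream is deterministic under ``config.master_seed``.
    Returns the per-trial results plus primary- and secondary-mode error
    summaries.
    """
    ss = np.random.SeedSequence(config.master_seed)
    speed_rng = np.random.default_rng(ss.spawn(1)[0])
    trial_seeds = ss.spawn(config.n_participants * len(config.paces))

    results: list[TrialResult] = []
    i = 0
    for pid in range(config.n_participants):
        for pace in config.paces:
            v = _draw_speed(speed_rng, pace.target_speed, pace.speed_sd)
            profile = walker.build_speed_profile(
                pace.label, v, config.profile_accel, config.protocol.path_length
            )
            data = simulate_trial(config, profile, pid, trial_seeds[i])
            results.append(
                estimate_trial(data, config, pace.target_speed, tuple(config.modes))
            )
            i += 1

    table = summarize(results)
    primary = table[table["mode"] == "primary"].reset_index(drop=True)
    secondary = table[table["mode"] == "secondary"].reset_index(drop=True)
    return results, primary, secondary


def speeds_table(results: list[TrialResult]) -> pd.DataFrame:
    """Per-trial summary table: one row per (participant, pace, sensor, mode)."""
    rows = []
    for r in results:
        rows.append(
            {
                "participant_id": r.participant_id,
                "pace": r.pace_label,
                "sensor": "gaitrite",
                "mode": "reference",
                "trial_mean_speed_mps": r.reference.trial_mean,
                "trial_sd_mps": r.reference.trial_sd,
                "n_walks_used": r.reference.n_walks_used,
            }
        )
        for (sensor, mode), e in sorted(r.estimates.items()):
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "pace": r.pace_label,
                    "sensor": sensor,
                    "mode": mode,
                    "trial_mean_speed_mps": e.trial_mean,
                    "trial_sd_mps": e.trial_sd,
                    "n_walks_used": e.n_walks_used,
                }
            )
    return pd.DataFrame(rows)


def walk_speeds_table(results: list[TrialResult]) -> pd.DataFrame:
    """Long-format per-walk speeds: (trial, sensor, mode, walk_index, speed)."""
    rows = []
    for r in results:
        for walk_idx, s in enumerate(r.reference.per_walk_speed):
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "pace": r.pace_label,
                    "sensor": "gaitrite",
                    "mode": "reference",
                    "walk_index": walk_idx,
                    "speed_mps": s,
                }
            )
        for (sensor, mode), e in sorted(r.estimates.items()):
            for walk_idx, s in enumerate(e.per_walk_speed):
                rows.append(
                    {
                        "participant_id": r.participant_id,
                        "pace": r.pace_label,
                        "sensor": sensor,
                        "mode": mode,
                        "walk_index": walk_idx,
                        "speed_mps": s,
                    }
                )
    return pd.DataFrame(rows)
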