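"""HDF5 persistence for simulated trials (one group per participant/pace).

Every file records the configuration hash and master seed as root attributes
so downstream tables can state their provenance.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from . import sensors as sens
from . import walker
from .comparison import TrialData
from .config import RunConfig, config_hash


def save_trials(path: str | Path, trials: list[TrialData], config: RunConfig, seed: int) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash(config)
        f.attrs["master_seed"] = seed
        for t in trials:
            g = f.create_group(f"trial_p{t.participant_id}_{t.pace_label}")
            g.attrs["participant_id"] = t.participant_id
            g.attrs["pace_label"] = t.pace_label
            g.attrs["steady_speed"] = t.steady_speed
            g.attrs["profile_accel"] = t.profile.accel

            tr = g.create_group("trajectory")
            tr.attrs["sample_rate"] = t.trajectory.sample_rate
            tr["position"] = t.trajectory.position
            tr["velocity"] = t.trajectory.velocity
            tr["walk_index"] = t.trajectory.walk_index

            gt = g.create_group("ground_truth")
            gt["per_walk_steady_speed"] = t.ground_truth.per_walk_steady_speed
            gt["mat_intervals"] = np.array(
                [iv if iv is not None else (np.nan, np.nan) for iv in t.ground_truth.mat_intervals]
            )
            gt["mat_segment_speeds"] = t.ground_truth.mat_segment_speeds
            gt.attrs["trial_mean_speed"] = t.ground_truth.trial_mean_speed

            cw = g.create_group("cw")
            cw.attrs["sample_rate"] = t.cw.sample_rate
            cw.attrs["start_time"] = t.cw.start_time
            cw["samples"] = t.cw.samples

            uwb = g.create_group("uwb")
            uwb["pulse_times"] = t.uwb.pulse_times
            uwb["bins"] = t.uwb.bins
            uwb["amplitudes"] = t.uwb.amplitudes
            uwb["background"] = t.uwb.background

            th = g.create_group("thermal")
            th["frame_times"] = t.thermal.frame_times
            th["frames"] = t.thermal.frames.astype(np.float32)

            mc = g.create_group("mocap")
            mc["frame_times"] = t.mocap.frame_times
            mc["xyz"] = t.mocap.xyz

            gr = g.create_group("gaitrite")
            rows = [
                (w, ft.heel_position, ft.toe_position, ft.contact_time)
                for w, feet in enumerate(t.footfalls.walks)
                for ft in feet
            ]
            gr["footfalls"] = np.array(rows, dtype=float) if rows else np.empty((0, 4))


def load_trials(path: str | Path, config: RunConfig) -> list[TrialData]:
    trials: list[TrialData] = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            fs = float(g["trajectory"].attrs["sample_rate"])
            position = g["trajectory/position"][:]
            traj = walker.Trajectory(
                sample_rate=fs,
                times=np.arange(position.size) / fs,
                position=position,
                velocity=g["trajectory/velocity"][:],
                walk_index=g["trajectory/walk_index"][:],
            )
            ivals = [
                None if np.isnan(a) else (float(a), float(b))
                for a, b in g["ground_truth/mat_intervals"][:]
            ]
            gt = walker.GroundTruth(
                per_walk_steady_speed=list(g["ground_truth/per_walk_steady_speed"][:]),
                mat_intervals=ivals,
                trial_mean_speed=float(g["ground_truth"].attrs["trial_mean_speed"]),
                mat_segment_speeds=list(g["ground_truth/mat_segment_speeds"][:]),
            )
            ff = g["gaitrite/footfalls"][:]
            n_walks = int(traj.walk_index.max()) + 1
            walks: list[list[sens.Footfall]] = [[] for _ in range(n_walks)]
            for w, heel, toe, tc in ff:
                walks[int(w)].append(sens.Footfall(heel, toe, tc))
            profile = walker.SpeedProfile(
                steady_speed=float(g.attrs["steady_speed"]),
                accel=float(g.attrs["profile_accel"]),
                pace_label=str(g.attrs["pace_label"]),
            )
            trials.append(
                TrialData(
                    participant_id=int(g.attrs["participant_id"]),
                    pace_label=str(g.attrs["pace_label"]),
                    steady_speed=float(g.attrs["steady_speed"]),
                    protocol=config.protocol,
                    profile=profile,
                    trajectory=traj,
                    ground_truth=gt,
                    cw=sens.CWSignal(
                        sample_rate=float(g["cw"].attrs["sample_rate"]),
                        samples=g["cw/samples"][:],
                        start_time=float(g["cw"].attrs["start_time"]),
                    ),
                    uwb=sens.RangeProfileStack(
                        pulse_times=g["uwb/pulse_times"][:],
                        bins=g["uwb/bins"][:],
                        amplitudes=g["uwb/amplitudes"][:],
                        background=g["uwb/background"][:],
                    ),
                    thermal=sens.ThermalFrames(
                        frame_times=g["thermal/frame_times"][:],
                        frames=g["thermal/frames"][:].astype(float),
                    ),
                    mocap=sens.HeadTrack(
                        frame_times=g["mocap/frame_times"][:], xyz=g["mocap/xyz"][:]
                    ),
                    footfalls=sens.FootfallSequence(walks=walks),
                )
            )
    return trials
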