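"""Speed estimators: STFT oracle, Doppler conversion, tracking, reference rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitsense as gs
from gaitsense.estimators import _walk_speed
from conftest import constant_velocity_trajectory


def dft_spectrogram_oracle(sig: gs.CWSignal, cfg: gs.STFTConfig):
    """Brute-force windowed DFT: explicit O(N^2) sum per column."""
    from scipy.signal import get_window

    fs = sig.sample_rate
    n_win = int(round(cfg.window_length * fs))
    n_hop = int(round(cfg.hop * fs))
    w = get_window(cfg.window, n_win, fftbins=True)
    n = np.arange(n_win)
    k = np.arange(cfg.fft_size)
    basis = np.exp(-2j * np.pi * np.outer(k, n) / cfg.fft_size)  # (nfft, nwin)
    cols = []
    for start in range(0, sig.samples.size - n_win + 1, n_hop):
        frame = w * sig.samples[start : start + n_win]
        cols.append(np.abs(basis @ frame) ** 2)
    return np.fft.fftshift(np.array(cols).T, axes=0)


class TestSTFT:
    CFG = gs.STFTConfig(window="hann", window_length=0.064, hop=0.032, fft_size=64)

    def _random_signal(self, rng, fs=500.0, dur=0.3):
        n = int(dur * fs)
        return gs.CWSignal(fs, rng.standard_normal(n) + 1j * rng.standard_normal(n))

    def test_matches_brute_force_dft_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            sig = self._random_signal(rng)
            spec = gs.stft_spectrogram(sig, self.CFG)
            oracle = dft_spectrogram_oracle(sig, self.CFG)
            scale = np.abs(oracle).max()
            assert np.max(np.abs(spec.power - oracle)) / scale < 1e-9

    def test_pure_tone_peaks_in_its_signed_bin(self):
        fs, f_tone = 1000.0, 96.0
        t = np.arange(int(2 * fs)) / fs
        sig = gs.CWSignal(fs, np.exp(2j * np.pi * f_tone * t))
        spec = gs.stft_spectrogram(sig, gs.STFTConfig())
        peak_freqs = spec.freqs[np.argmax(spec.power, axis=0)]
        bin_w = fs / gs.STFTConfig().fft_size
        assert np.all(np.abs(peak_freqs - f_tone) <= bin_w)

    def test_zero_signal_gives_zero_power(self):
        sig = gs.CWSignal(500.0, np.zeros(200, dtype=complex))
        spec = gs.stft_spectrogram(sig, self.CFG)
        assert np.all(spec.power == 0.0)

    def test_column_energy_matches_windowed_frame(self):
        """Parseval: sum |X_k|^2 / nfft equals the tapered frame's energy."""
        rng = np.random.default_rng(1)
        sig = self._random_signal(rng)
        spec = gs.stft_spectrogram(sig, self.CFG)
        from scipy.signal import get_window

        n_win = int(round(self.CFG.window_length * sig.sample_rate))
        w = get_window(self.CFG.window, n_win, fftbins=True)
        frame0 = w * sig.samples[:n_win]
        assert spec.power[:, 0].sum() / self.CFG.fft_size == pytest.approx(
            np.sum(np.abs(frame0) ** 2), rel=1e-12
        )

    def test_short_signal_rejected(self):
        sig = gs.CWSignal(500.0, np.zeros(10, dtype=complex))
        with pytest.raises(ValueError, match="shorter"):
            gs.stft_spectrogram(sig, self.CFG)


class TestCWSpeed:
    def _tone_spec(self, v, quiet_config, dur=6.0):
        traj = constant_velocity_trajectory(-v, 6.5, dur)  # walking toward radar
        sig = gs.simulate_cw_signal(traj, quiet_config.protocol, quiet_config.cw, 0)
        return gs.stft_spectrogram(sig, gs.STFTConfig())

    def test_recovers_constant_velocity_within_bin_quantum(self, quiet_config):
        stft = gs.STFTConfig()
        quantum = quiet_config.cw.c / (2 * quiet_config.cw.f0 * stft.window_length)
        for v in (0.3, 0.6, 1.0):
            spec = self._tone_spec(v, quiet_config)
            _, est = gs.estimate_speed_cw(
                spec, quiet_config.cw, [(0.5, 5.5)], doppler_factor=2
            )
            assert abs(est.trial_mean - v) <= quantum

    def test_approaching_walker_has_positive_doppler(self, quiet_config):
        spec = self._tone_spec(0.6, quiet_config)
        dop, _ = gs.estimate_speed_cw(spec, quiet_config.cw, [(0.5, 5.5)])
        assert dop.delta_f[0] > 0

    def test_doppler_factor_scales_speed_exactly_twofold(self, quiet_config):
        spec = self._tone_spec(0.6, quiet_config)
        _, one_way = gs.estimate_speed_cw(spec, quiet_config.cw, [(0.5, 5.5)], doppler_factor=1)
        _, two_way = gs.estimate_speed_cw(spec, quiet_config.cw, [(0.5, 5.5)], doppler_factor=2)
        assert one_way.trial_mean == pytest.approx(2 * two_way.trial_mean, rel=1e-12)

    def test_stationary_target_speed_zero(self, quiet_config):
        spec = self._tone_spec(0.0, quiet_config)
        _, est = gs.estimate_speed_cw(spec, quiet_config.cw, [(0.5, 5.5)])
        assert est.trial_mean == pytest.approx(0.0, abs=1e-9)

    def test_empty_window_flagged_unusable(self, quiet_config):
        spec = self._tone_spec(0.6, quiet_config)
        _, est = gs.estimate_speed_cw(spec, quiet_config.cw, [None, (0.5, 5.5)])
        assert np.isnan(est.per_walk_speed[0])
        assert est.n_walks_used == 1


class TestUWBSpeed:
    def test_stationary_target_constant_track(self, quiet_config):
        traj = constant_velocity_trajectory(0.0, 2.0, 2.0)
        stack = gs.simulate_uwb_stack(traj, quiet_config.protocol, quiet_config.uwb, 0)
        track = gs.uwb_range_track(stack)
        assert np.all(np.abs(track.range_m[track.valid] - 3.0) <= 0.05)

    def test_clutter_only_stack_is_all_missing(self, quiet_config):
        # static clutter, no noise, target out of range: gating leaves nothing
        uwb = quiet_config.uwb.model_copy(update={"clutter_amplitude": 0.05})
        traj = constant_velocity_trajectory(0.0, 100.0, 2.0)  # out of range
        stack = gs.simulate_uwb_stack(traj, quiet_config.protocol, uwb, 1)
        with pytest.raises(ValueError, match="missing"):
            gs.uwb_range_track(stack)

    def test_track_slope_matches_plateau_speed(self, normal_trial_quiet):
        trial = normal_trial_quiet
        track = gs.uwb_range_track(trial.uwb)
        est = gs.estimate_speed_uwb(
            track, trial.ground_truth.mat_intervals, mode="secondary"
        )
        assert est.trial_mean == pytest.approx(1.0, rel=0.02)

    def test_primary_underestimates_plateau(self, normal_trial_quiet):
        trial = normal_trial_quiet
        track = gs.uwb_range_track(trial.uwb)
        est = gs.estimate_speed_uwb(track, gs.walk_spans(trial.trajectory), mode="primary")
        assert est.trial_mean < 1.0

    def test_sparse_walk_flagged_unusable(self, normal_trial_quiet):
        track = gs.uwb_range_track(normal_trial_quiet.uwb)
        est = gs.estimate_speed_uwb(track, [(0.0, 0.01)], mode="secondary")
        assert est.n_walks_used == 0


class TestThermalSpeed:
    def test_uniform_frames_sum_to_value_times_pixels(self):
        frames = gs.ThermalFrames(
            frame_times=np.arange(4) / 13.0, frames=np.full((4, 6, 8), 2.5)
        )
        assert np.allclose(gs.thermal_intensity_series(frames), 2.5 * 48)

    def test_intensity_sum_is_linear_in_offset(self, normal_trial_quiet):
        frames = normal_trial_quiet.thermal
        s0 = gs.thermal_intensity_series(frames)
        shifted = gs.ThermalFrames(frames.frame_times, frames.frames + 1.0)
        n_px = frames.frames.shape[1] * frames.frames.shape[2]
        assert np.allclose(gs.thermal_intensity_series(shifted), s0 + n_px)

    def test_secondary_recovers_slow_speed(self, slow_trial_quiet, quiet_config):
        trial = slow_trial_quiet
        series = gs.thermal_intensity_series(trial.thermal)
        off = gs.off_mat_time_per_round_trip(trial.protocol, trial.profile)
        est = gs.estimate_speed_thermal(
            series, quiet_config.thermal, trial.protocol, mode="secondary",
            off_mat_time_rt=off,
        )
        # one 13 fps frame over a ~16.7 s mat crossing: ~0.5% quantum
        assert est.trial_mean == pytest.approx(0.6, rel=0.01)

    def test_primary_underestimates_through_dwells(self, normal_trial_quiet, quiet_config):
        series = gs.thermal_intensity_series(normal_trial_quiet.thermal)
        est = gs.estimate_speed_thermal(
            series, quiet_config.thermal, normal_trial_quiet.protocol, mode="primary"
        )
        assert est.trial_mean < 1.0

    def test_wrong_extremum_count_errors_with_count(self, quiet_config):
        series = np.ones(100)
        with pytest.raises(ValueError, match="found 0"):
            gs.estimate_speed_thermal(
                series, quiet_config.thermal, quiet_config.protocol, mode="secondary"
            )

    def test_quantisation_step_at_fifteen_fps(self):
        # 1 m/s at 15 frames/s resolves to ~0.07 m/s
        assert gs.thermal_speed_resolution(1.0, 15.0) == pytest.approx(0.0667, abs=5e-4)
        assert round(gs.thermal_speed_resolution(1.0, 15.0), 2) == 0.07


class TestSuitSpeed:
    def test_secondary_window_inside_plateau_is_exact(self, normal_trial_quiet):
        est = gs.estimate_speed_suit(normal_trial_quiet.mocap, mode="secondary")
        assert est.trial_mean == pytest.approx(1.0, abs=1e-9)

    def test_primary_strictly_below_plateau(self, normal_trial_quiet):
        est = gs.estimate_speed_suit(normal_trial_quiet.mocap, mode="primary")
        assert est.n_walks_used == 6
        assert est.trial_mean < 1.0

    def test_extrema_spacing_consistent_with_frame_rate(self, normal_trial_quiet):
        """Walk duration from extrema spacing: frames / 125 per walk + dwell."""
        x = normal_trial_quiet.mocap.xyz[:, 0]
        prof = normal_trial_quiet.profile
        walk_plus_dwell = prof.walk_duration(7.0) + 2.0
        from scipy.signal import find_peaks

        hi, _ = find_peaks(x, prominence=1.0)
        lo, _ = find_peaks(-x, prominence=1.0)
        spacing = np.diff(np.sort(np.concatenate([hi, lo]))) / 125.0
        assert np.allclose(spacing, walk_plus_dwell, atol=0.2)

    def test_flat_track_has_no_walks(self, quiet_config):
        track = gs.HeadTrack(
            frame_times=np.arange(500) / 125.0, xyz=np.zeros((500, 3))
        )
        with pytest.raises(ValueError, match="segments"):
            gs.estimate_speed_suit(track, mode="primary")


def make_walks(speeds, distance=4.0):
    """Two-footfall walks engineered to read back the given speeds exactly."""
    walks = []
    for s in speeds:
        walks.append(
            [
                gs.Footfall(0.0, 0.25, 0.0),
                gs.Footfall(distance - 0.25, distance, (distance) / s),
            ]
        )
    return gs.FootfallSequence(walks=walks)


class TestGaitRite:
    def test_identical_walks_mean_with_none_omitted(self):
        ref = gs.gaitrite_speed(make_walks([1.0] * 6))
        assert ref.trial_mean == pytest.approx(1.0)
        assert ref.n_walks_used == 6
        assert ref.omitted_walks == []

    def test_doubled_walk_omitted_five_walk_mean(self):
        ref = gs.gaitrite_speed(make_walks([1.0] * 5 + [2.05]))
        assert ref.n_walks_used == 5
        assert ref.omitted_walks == [5]
        assert ref.trial_mean == pytest.approx(1.0)

    def test_short_walk_unusable_counts_as_omitted(self):
        seq = make_walks([1.0] * 5)
        seq.walks.append([gs.Footfall(0.0, 0.25, 0.0)])  # single footfall
        ref = gs.gaitrite_speed(seq)
        assert ref.n_walks_used == 5
        assert 5 in ref.omitted_walks

    def test_noise_free_constant_speed_matches_plateau(self, normal_trial_quiet):
        cfg = gs.GaitRiteConfig(spatial_sd=0.0, sample_rate=1e9)
        seq = gs.simulate_footfalls(
            normal_trial_quiet.trajectory, normal_trial_quiet.protocol, cfg, 0
        )
        ref = gs.gaitrite_speed(seq)
        assert ref.trial_mean == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        speeds=st.lists(st.floats(0.3, 3.0), min_size=3, max_size=8),
    )
    def test_omission_rule_is_idempotent(self, speeds):
        """Re-applying the rule to the retained walks omits nothing further."""
        ref = gs.gaitrite_speed(make_walks(speeds))
        kept = [s for i, s in enumerate(speeds) if i not in ref.omitted_walks]
        if len(kept) < 2:
            return
        again = gs.gaitrite_speed(make_walks(kept))
        assert again.omitted_walks == []
        assert again.trial_mean == pytest.approx(ref.trial_mean, rel=1e-9)

    def test_walk_speed_helper_reads_heel_to_toe(self):
        feet = [gs.Footfall(0.0, 0.25, 0.0), gs.Footfall(3.75, 4.0, 4.0)]
        assert _walk_speed(feet) == pytest.approx(1.0)
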