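"""Insole stride detection: normalization, filtering, locking period,
peak validation, force cross-checks, gait parameters."""

import numpy as np
import pytest

from tugkit import (
    InsoleRecording,
    PreprocessConfig,
    compute_gait_parameters,
    detect_stride_peaks,
    detect_sts_phases,
    locking_period,
    lowpass_ay,
    normalize_recording,
    stance_onsets,
    validate_with_force,
)
from tugkit.insole import StrideEvents


def make_recording(ay, forces=None, fs=100.0):
    ay = np.asarray(ay, float)
    n = ay.size
    if forces is None:
        forces = np.column_stack([np.linspace(0, 1, n)] * 3)
    return InsoleRecording(np.arange(n) / fs, ay, forces, fs)


def run_detection(insole, config=None):
    config = config or PreprocessConfig()
    norm = normalize_recording(insole)
    ay = lowpass_ay(norm.ay, norm.sample_rate_hz, config)
    _, lockp = locking_period(ay, norm.sample_rate_hz)
    return norm, detect_stride_peaks(ay, norm.sample_rate_hz, lockp, config), lockp


class TestNormalize:
    def test_zscore_uses_population_sd(self):
        rec = make_recording([1.0, 2.0, 3.0])
        norm = normalize_recording(rec)
        assert norm.ay.mean() == pytest.approx(0.0)
        assert np.std(norm.ay) == pytest.approx(1.0)  # divide by N, not N-1

    def test_total_force_scaled_to_unit_max(self):
        f = np.column_stack([[1.0, 2, 4], [0.5, 1, 2], [0.5, 1, 2]])
        rec = make_recording([0.0, 1.0, 2.0], forces=f)
        norm = normalize_recording(rec)
        assert np.allclose(norm.total_force, [0.25, 0.5, 1.0])

    def test_force_subset_selects_channels(self):
        f = np.column_stack([[1.0, 2, 4], [10.0, 10, 10], [1.0, 2, 4]])
        rec = make_recording([0.0, 1.0, 2.0], forces=f)
        norm = normalize_recording(rec, force_subset=(0, 2))
        assert np.allclose(norm.total_force, [0.25, 0.5, 1.0])

    def test_constant_ay_rejected(self):
        with pytest.raises(ValueError):
            normalize_recording(make_recording([1.0, 1.0, 1.0]))

    def test_all_zero_force_rejected(self):
        rec = make_recording([0.0, 1.0, 2.0], forces=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            normalize_recording(rec)


class TestLowpass:
    def test_constant_signal_unchanged(self):
        out = lowpass_ay(np.full(200, 3.3), 100.0)
        assert np.allclose(out, 3.3, atol=1e-9)

    def test_frequency_selectivity(self):
        """1 Hz passes nearly intact, 30 Hz is attenuated >= 20 dB."""
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        cfg = PreprocessConfig(butterworth_cutoff_hz=5.0, median_window=3)
        low = np.sin(2 * np.pi * 1.0 * t)
        high = np.sin(2 * np.pi * 30.0 * t)
        out_low = lowpass_ay(low, fs, cfg)
        out_high = lowpass_ay(high, fs, cfg)
        mid = slice(200, 800)
        amp_low = np.max(np.abs(out_low[mid]))
        amp_high = np.max(np.abs(out_high[mid]))
        assert abs(amp_low - 1.0) < 0.05
        assert amp_high < 0.1  # >= 20 dB down

    def test_single_sample_spike_removed_by_median(self):
        x = np.zeros(300)
        x[150] = 50.0
        out = lowpass_ay(x, 100.0)
        assert np.max(np.abs(out)) < 1.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_ay(np.zeros(100), 100.0, PreprocessConfig(butterworth_cutoff_hz=60.0))


class TestLockingPeriod:
    def test_sine_crossing_interval(self):
        fs = 100.0
        t = np.arange(0, 5, 1 / fs)
        crossings, lockp = locking_period(np.sin(2 * np.pi * t), fs)
        assert lockp == pytest.approx(0.5, rel=0.02)
        assert np.allclose(np.diff(crossings) / fs, 0.5, atol=0.02)

    def test_all_positive_signal_rejected(self):
        with pytest.raises(ValueError):
            locking_period(np.ones(100) + 0.1 * np.sin(np.arange(100)) ** 2, 100.0)

    def test_simulator_lockp_quarter_stride_time(self, clean_trial):
        """Four sign changes per stride (two per step) make the mean
        inter-crossing interval a quarter of the stride time."""
        _, insole, truth = clean_trial
        norm = normalize_recording(insole)
        ay = lowpass_ay(norm.ay, norm.sample_rate_hz)
        walking = (insole.time > truth.heel_strikes[0]) & (
            insole.time < truth.heel_strikes[-1]
        )
        _, lockp = locking_period(ay[walking], norm.sample_rate_hz)
        assert lockp == pytest.approx(truth.stride_times.mean() / 4, rel=0.10)


class TestDetectStridePeaks:
    def test_simulator_counts_match_truth(self, clean_trial):
        _, insole, truth = clean_trial
        _, events, _ = run_detection(insole)
        assert int(events.valid.sum()) == truth.n_strides + 1
        assert events.n_strides == truth.n_strides

    def test_close_second_peak_invalidated(self):
        """Two shape-alike peaks closer than lockP: the later one is zeroed."""
        fs = 100.0
        t = np.arange(0, 6, 1 / fs)
        base = np.sin(2 * np.pi * 0.5 * t)  # crossings 1 s apart -> lockP 1 s
        x = base.copy()
        # two sharp peaks 0.5 s (= 0.5 lockP) apart riding the first crest
        for c in (0.4, 0.9):
            x += 3.0 * np.exp(-((t - c) ** 2) / (2 * 0.03**2))
        _, lockp = locking_period(base, fs)
        events = detect_stride_peaks(x, fs, lockp, PreprocessConfig())
        sharp = [j for j, ti in enumerate(events.times) if abs(ti - 0.4) < 0.1
                 or abs(ti - 0.9) < 0.1]
        assert len(sharp) == 2
        first, second = sorted(sharp, key=lambda j: events.times[j])
        assert events.valid[first]
        assert not events.valid[second]

    def test_single_valid_peak_gives_zero_strides(self):
        fs = 100.0
        t = np.arange(0, 4, 1 / fs)
        x = 0.05 * np.sin(2 * np.pi * 1.0 * t)
        x += 3.0 * np.exp(-((t - 2.0) ** 2) / (2 * 0.05**2))
        _, lockp = locking_period(x, fs)
        events = detect_stride_peaks(x, fs, lockp, PreprocessConfig())
        assert int(events.valid.sum()) == 1
        assert events.n_strides == 0

    def test_stride_count_rule_and_boundaries(self, noisy_trial):
        _, insole, truth = noisy_trial
        _, events, lockp = run_detection(insole)
        assert events.n_strides == max(0, int(events.valid.sum()) - 1)
        bounds = events.stride_boundaries
        for (a0, b0), (a1, b1) in zip(bounds[:-1], bounds[1:]):
            assert b0 <= a1 + 1e-12
        assert bounds[0][0] >= insole.time[0]
        assert bounds[-1][1] <= insole.time[-1]
        # validity is idempotent: every retained gap respects the lower bound
        assert np.all(np.diff(events.valid_times) >= lockp - 1e-12)

    def test_counts_stable_across_seeds(self):
        from tugkit import SimulationParams, simulate_tug

        exact = 0
        for seed in range(15):
            p = SimulationParams(seed=seed, radar_noise_sd_m=0.0,
                                 ay_noise_sd=0.0, force_noise_sd=0.0)
            _, insole, truth = simulate_tug(p)
            _, events, _ = run_detection(insole)
            exact += events.n_strides == truth.n_strides
        assert exact == 15


class TestForceValidation:
    def test_simulator_agreement(self, clean_trial):
        _, insole, truth = clean_trial
        norm, events, _ = run_detection(insole)
        report = validate_with_force(norm.total_force, events, norm.sample_rate_hz)
        assert report.agreement
        assert report.force_cycles == truth.n_strides

    def test_deleted_stance_cycle_breaks_agreement(self, clean_trial):
        _, insole, truth = clean_trial
        norm, events, _ = run_detection(insole)
        f = norm.total_force.copy()
        # flatten one mid-walking swing (fill it at stance level)
        hs = truth.heel_strikes
        sel = (norm.time > hs[1]) & (norm.time < hs[2])
        f[sel] = 1.0
        report = validate_with_force(f, events, norm.sample_rate_hz)
        assert not report.agreement
        assert report.discrepancy == 1

    def test_constant_force_has_zero_cycles(self, clean_trial):
        _, insole, _ = clean_trial
        norm, events, _ = run_detection(insole)
        report = validate_with_force(np.ones_like(norm.total_force), events,
                                     norm.sample_rate_hz)
        assert report.force_cycles == 0
        assert not report.agreement

    def test_unnormalized_force_rejected(self, clean_trial):
        _, insole, _ = clean_trial
        norm, events, _ = run_detection(insole)
        with pytest.raises(ValueError):
            validate_with_force(norm.total_force * 3.0, events, norm.sample_rate_hz)


class TestStsPhases:
    @staticmethod
    def iou(a, b):
        inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
        union = max(a[1], b[1]) - min(a[0], b[0])
        return inter / union

    def test_simulator_phases_overlap_truth(self, clean_trial):
        _, insole, truth = clean_trial
        norm = normalize_recording(insole)
        s2st, st2s = detect_sts_phases(norm.total_force, norm.sample_rate_hz)
        assert self.iou(s2st, truth.motion_phases["sit_to_stand"]) >= 0.7
        assert self.iou(st2s, truth.motion_phases["stand_to_sit"]) >= 0.7

    def test_constant_force_rejected(self):
        with pytest.raises(ValueError):
            detect_sts_phases(np.ones(1000), 100.0)

    def test_monotone_rise_gives_s2st_only(self):
        f = np.concatenate([np.full(300, 0.2), np.linspace(0.2, 1.0, 200),
                            np.full(300, 1.0)])
        with pytest.raises(ValueError, match="stand-to-sit"):
            detect_sts_phases(f, 100.0)

    def test_stance_onsets_track_heel_strikes(self, clean_trial):
        _, insole, truth = clean_trial
        norm = normalize_recording(insole)
        onsets = stance_onsets(norm.total_force, norm.sample_rate_hz)
        # every heel strike after the first has a force onset within 30 ms
        for hs in truth.heel_strikes[1:]:
            assert np.min(np.abs(onsets - hs)) < 0.03


class TestGaitParameters:
    @staticmethod
    def synthetic_events(boundaries):
        n = len(boundaries) + 1
        times = np.array([b[0] for b in boundaries] + [boundaries[-1][1]])
        return StrideEvents(
            zero_crossings=np.array([], dtype=int),
            locking_period_s=0.3,
            peak_indices=np.arange(n),
            peak_values=np.ones(n),
            pl=np.ones(n),
            pr=np.ones(n),
            valid=np.ones(n, dtype=bool),
            times=times,
        )

    def test_cadence_formula(self):
        events = self.synthetic_events([(0.0, 1.2)])
        gp = compute_gait_parameters(events, np.array([1.3]))
        assert gp.cadence_steps_min[0] == pytest.approx(100.0)  # 60*2/1.2

    def test_stride_speed(self):
        events = self.synthetic_events([(0.0, 1.0)])
        gp = compute_gait_parameters(events, np.array([1.3]))
        assert gp.stride_speed_mps[0] == pytest.approx(1.3)

    def test_length_mismatch_rejected(self):
        events = self.synthetic_events([(0.0, 1.0), (1.0, 2.0)])
        with pytest.raises(ValueError):
            compute_gait_parameters(events, np.array([1.3]))
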