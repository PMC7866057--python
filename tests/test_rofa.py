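"""ROFA gait-deviation scoring: ratios, scores, bands, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tugkit import (
    BaselineStats,
    build_baseline,
    classify_risk,
    compute_ratio,
    compute_sk,
    compute_tug_score,
    score_trial,
)
from tugkit.rofa import BaselineEntry


class TestRatioAndScore:
    def test_at_baseline_mean(self):
        entry = BaselineEntry(1.2, 0.1)
        assert compute_ratio(1.2, entry) == 0.0
        assert compute_sk(0.0) == 100.0

    def test_two_sigma_deviation(self):
        entry = BaselineEntry(1.2, 0.1)
        assert compute_ratio(1.4, entry) == pytest.approx(2.0)

    def test_ten_points_per_sigma(self):
        assert compute_sk(1.0) == 90.0

    def test_clamped_at_zero(self):
        assert compute_sk(15.0) == 0.0

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            compute_sk(-0.1)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            BaselineEntry(1.2, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 20.0), st.floats(0.0, 20.0))
    def test_score_monotone_in_deviation(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert compute_sk(hi) <= compute_sk(lo)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(0.5, 2.0), st.floats(0.05, 0.5))
    def test_scale_invariance(self, scale, mean, sd):
        """Rescaling a parameter together with its baseline leaves Rk alone."""
        gk = mean + 1.7 * sd
        r0 = compute_ratio(gk, BaselineEntry(mean, sd))
        r1 = compute_ratio(scale * gk, BaselineEntry(scale * mean, scale * sd))
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestCompositeScore:
    def test_perfect_scores(self):
        assert compute_tug_score(np.array([100.0] * 4)) == 100.0

    def test_weighted_mean(self):
        assert compute_tug_score(np.array([80.0, 100.0]), np.array([0.5, 0.5])) == 90.0

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(ValueError):
            compute_tug_score(np.array([50.0, 50.0]), np.array([0.5, 0.4]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_tug_score(np.array([]))


class TestRiskBands:
    @pytest.mark.parametrize(
        "score,band",
        [
            (0.0, "very high"),
            (24.0, "very high"),
            (24.999, "very high"),
            (25.0, "high"),
            (49.9, "high"),
            (50.0, "medium"),
            (75.0, "low"),
            (99.999, "low"),
            (100.0, "very low"),
        ],
    )
    def test_band_edges(self, score, band):
        assert classify_risk(score) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(101.0)
        with pytest.raises(ValueError):
            classify_risk(-0.1)


class TestBaseline:
    def test_pooled_mean_and_sample_sd(self):
        trials = [{"stride_length_m": np.array([1.0, 1.2, 1.4])}]
        base = build_baseline(trials)
        entry = base.parameters["stride_length_m"]
        assert entry.mean == pytest.approx(1.2)
        assert entry.sd == pytest.approx(np.std([1.0, 1.2, 1.4], ddof=1))

    def test_zero_variance_parameter_flagged_and_excluded(self):
        trials = [
            {"stride_length_m": np.array([1.3, 1.3]), "stride_time_s": np.array([1.0, 1.1])},
            {"stride_length_m": np.array([1.3, 1.3]), "stride_time_s": np.array([1.2, 0.9])},
        ]
        with pytest.warns(UserWarning, match="zero pooled variance"):
            base = build_baseline(trials)
        assert "stride_length_m" not in base.parameters
        assert "stride_time_s" in base.parameters

    def test_simulator_baseline_recovers_planted_mean(self):
        """Baseline over 5 trials with strides drawn near 1.3 +- 0.05 m."""
        rng = np.random.default_rng(11)
        trials = [
            {"stride_length_m": rng.normal(1.3, 0.05, 12)} for _ in range(5)
        ]
        base = build_baseline(trials)
        assert base.parameters["stride_length_m"].mean == pytest.approx(1.3, abs=0.02)

    def test_roundtrip_dict(self):
        base = build_baseline([{"a": np.array([1.0, 2.0, 3.0])}])
        again = BaselineStats.from_dict(base.to_dict())
        assert again.parameters["a"].mean == base.parameters["a"].mean


class TestScoreTrial:
    @pytest.fixture
    def baseline(self):
        return BaselineStats(
            parameters={
                "stride_length_m": BaselineEntry(1.3, 0.05),
                "stride_time_s": BaselineEntry(1.1, 0.04),
            }
        )

    def test_trial_at_baseline_means_scores_100(self, baseline):
        trial = {
            "stride_length_m": np.full(5, 1.3),
            "stride_time_s": np.full(5, 1.1),
        }
        result = score_trial(trial, baseline)
        assert result.tug_score == 100.0
        assert result.risk_band == "very low"

    def test_one_sigma_everywhere_scores_90(self, baseline):
        trial = {
            "stride_length_m": np.full(5, 1.35),
            "stride_time_s": np.full(5, 1.14),
        }
        result = score_trial(trial, baseline)
        assert result.tug_score == pytest.approx(90.0)
        assert result.risk_band == "low"

    def test_no_overlap_rejected(self, baseline):
        with pytest.raises(ValueError):
            score_trial({"cadence_steps_min": np.array([100.0])}, baseline)

    def test_score_monotone_in_parameter_deviation(self, baseline):
        scores = []
        for delta in (0.0, 0.05, 0.1, 0.2, 0.5):
            trial = {
                "stride_length_m": np.full(3, 1.3 + delta),
                "stride_time_s": np.full(3, 1.1),
            }
            scores.append(score_trial(trial, baseline).tug_score)
        assert np.all(np.diff(scores) <= 0)

    def test_score_always_in_range(self, baseline):
        trial = {
            "stride_length_m": np.full(3, 99.0),  # absurd deviation
            "stride_time_s": np.full(3, 1.1),
        }
        result = score_trial(trial, baseline)
        assert 0.0 <= result.tug_score <= 100.0

    def test_trial_mean_mode(self, baseline):
        """Scoring the trial-mean parameter instead of per-stride values."""
        trial = {"stride_length_m": np.array([1.25, 1.35])}
        per_stride = score_trial(trial, baseline, per_stride=True)
        trial_mean = score_trial(trial, baseline, per_stride=False)
        assert trial_mean.tug_score == pytest.approx(100.0)
        assert per_stride.tug_score == pytest.approx(90.0)

    def test_healthy_simulated_baseline_scores_low_risk(self):
        """Self-scored healthy trials stay above the low-risk floor."""
        from tugkit import SimulationParams, simulate_tug, trial_parameters

        tables = []
        for seed in range(5):
            radar, insole, _ = simulate_tug(SimulationParams(seed=seed))
            tables.append(trial_parameters(radar, insole))
        base = build_baseline(tables)
        scores = [score_trial(t, base).tug_score for t in tables]
        assert np.mean(scores) >= 75.0
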