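"""Reach windows, d' modulation, duration coupling, and reach-start
detection."""

import numpy as np
import pandas as pd
import pytest

import crossarea as ca
from crossarea.behavior import (reach_windows, ca_modulation,
                                duration_modulation_slope,
                                label_detection_samples, fit_reach_detector,
                                roc_auc, prediction_timecourse,
                                median_separability)


class TestReachWindows:
    def test_window_arithmetic(self):
        reach, base = reach_windows(10.0, 10.2)
        assert reach == (pytest.approx(9.9), pytest.approx(10.3))
        assert base == (pytest.approx(8.5), pytest.approx(8.9))

    def test_degenerate_grasp_equals_reach(self):
        reach, base = reach_windows(5.0, 5.0)
        assert reach == (pytest.approx(4.9), pytest.approx(5.1))
        assert base == (pytest.approx(3.7), pytest.approx(3.9))

    def test_baseline_before_data_raises(self):
        with pytest.raises(ValueError):
            reach_windows(1.0, 1.2, data_start_s=0.5)


def _segments(reach_vals, base_vals, dt=0.1):
    """Build a trajectory whose bins in the two windows carry given values."""
    n_r, n_b = len(reach_vals), len(base_vals)
    base_w = (0.0, n_b * dt)
    reach_w = (base_w[1] + 1.0, base_w[1] + 1.0 + n_r * dt)
    t = np.concatenate([base_w[0] + dt * (np.arange(n_b) + 0.5),
                        reach_w[0] + dt * (np.arange(n_r) + 0.5)])
    sig = np.concatenate([base_vals, reach_vals]).astype(float)
    return sig, t, reach_w, base_w


class TestCaModulation:
    def test_printed_equation_fixed_point(self):
        # baseline (-2,0,2): median 0, mean 0, sd 2; reach (0,2,4): mean 2,
        # sd 2 -> denominator 0.5*sqrt(2+2) = 1 -> d' = 2
        sig, t, rw, bw = _segments([0.0, 2.0, 4.0], [-2.0, 0.0, 2.0])
        rec = ca_modulation(sig, t, rw, bw)
        assert rec.d_prime == pytest.approx(2.0)

    def test_identical_segments_give_zero(self):
        sig, t, rw, bw = _segments([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ca_modulation(sig, t, rw, bw).d_prime == pytest.approx(0.0)

    def test_negation_about_baseline_median_flips_sign(self):
        sig, t, rw, bw = _segments([0.5, 1.5, 2.5], [-1.0, 0.0, 1.0])
        d1 = ca_modulation(sig, t, rw, bw).d_prime
        d2 = ca_modulation(-sig, t, rw, bw).d_prime
        assert d1 == pytest.approx(-d2)

    def test_printed_denominator_scales_as_sqrt(self):
        # under the as-printed denominator, scaling the signal by c scales
        # d' by sqrt(c) (non-standard but faithful)
        sig, t, rw, bw = _segments([0.0, 2.0, 4.0], [-2.0, 0.0, 2.0])
        d1 = ca_modulation(sig, t, rw, bw).d_prime
        d4 = ca_modulation(4.0 * sig, t, rw, bw).d_prime
        assert d4 == pytest.approx(2.0 * d1)

    def test_pooled_variant_is_scale_invariant(self):
        sig, t, rw, bw = _segments([0.0, 2.0, 4.0], [-2.0, 0.0, 2.0])
        d1 = ca_modulation(sig, t, rw, bw, variant="pooled").d_prime
        d4 = ca_modulation(4.0 * sig, t, rw, bw, variant="pooled").d_prime
        assert d4 == pytest.approx(d1)
        assert d1 == pytest.approx(1.0)   # (2-0)/sqrt((4+4)/2)

    def test_constant_segments_flagged_invalid(self):
        sig, t, rw, bw = _segments([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        rec = ca_modulation(sig, t, rw, bw)
        assert not rec.valid and np.isnan(rec.d_prime)

    def test_constant_offset_invariance(self):
        sig, t, rw, bw = _segments([0.0, 2.0, 4.0], [-2.0, 0.0, 2.0])
        d1 = ca_modulation(sig, t, rw, bw).d_prime
        d2 = ca_modulation(sig + 7.5, t, rw, bw).d_prime
        assert d1 == pytest.approx(d2)


class TestDurationSlope:
    def _records(self, beta, n, rng, noise=0.25):
        dur = rng.lognormal(np.log(0.25), 0.3, n)
        d = 2.0 * dur ** beta * rng.lognormal(0.0, noise, n)
        stage = np.where(rng.random(n) < 0.5, "early", "late")
        return pd.DataFrame({"trial_id": np.arange(n), "d_prime": d,
                             "reach_duration_s": dur, "stage": stage,
                             "animal_id": "r1", "valid": True})

    def test_planted_slope_recovered(self, rng):
        df = self._records(-0.25, 500, rng)
        slope, t, p, _ = duration_modulation_slope(df)
        assert slope == pytest.approx(-0.25, abs=0.08)

    def test_duration_independent_null_covers_zero(self, rng):
        cover = 0
        for _ in range(30):
            df = self._records(0.0, 200, rng)
            slope, t, p, _ = duration_modulation_slope(df)
            cover += p > 0.05
        assert cover >= 24

    def test_negative_dprime_trials_excluded(self, rng):
        df = self._records(-0.25, 100, rng)
        df.loc[:9, "d_prime"] = -1.0
        slope, t, p, n_excluded = duration_modulation_slope(df)
        assert n_excluded == 10

    def test_all_nonpositive_raises(self):
        df = pd.DataFrame({"trial_id": [0, 1], "d_prime": [-1.0, -2.0],
                           "reach_duration_s": [0.2, 0.3],
                           "stage": ["late", "late"], "animal_id": "r",
                           "valid": [True, True]})
        with pytest.raises(ValueError):
            duration_modulation_slope(df)


class TestDetectionLabels:
    def _session_like(self, n_trials, rt=3.0):
        starts = 10.0 + 20.0 * np.arange(n_trials)
        trials = ca.make_trial_table(starts - rt, starts, starts + 0.2)
        traj = {}
        for i, rs in enumerate(starts):
            t = rs + np.arange(-2.5, 1.0, 0.1) + 0.05
            traj[i] = (t, np.zeros_like(t))
        return trials, traj

    def test_class_counts_19_to_4_per_trial(self):
        trials, traj = self._session_like(10)
        X, y, rep = label_detection_samples(trials, traj)
        assert rep["class_counts"] == (190, 40)

    def test_short_reaction_time_truncates_pre_window(self):
        trials, traj = self._session_like(5, rt=1.0)
        X, y, rep = label_detection_samples(trials, traj)
        assert rep["n_truncated"] == 5
        assert rep["class_counts"][0] < 5 * 19

    def test_no_valid_trials_raises(self):
        trials, _ = self._session_like(3)
        with pytest.raises(ValueError):
            label_detection_samples(trials, {})


class TestDetector:
    def test_perfect_separation_auc_one_with_ridge_flag(self):
        X = np.concatenate([np.zeros(50), np.ones(50)])[:, None]
        y = np.concatenate([np.zeros(50), np.ones(50)])
        model, scores = fit_reach_detector(X, y)
        assert roc_auc(scores, y).auc == 1.0
        assert model.ridge_fallback

    def test_shuffled_labels_auc_near_half(self, rng):
        X = rng.standard_normal((1000, 2))
        y = rng.integers(0, 2, 1000)
        model, scores = fit_reach_detector(X, y)
        assert roc_auc(scores, y).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            fit_reach_detector(rng.standard_normal((10, 1)), np.zeros(10))


class TestRocAuc:
    def test_constant_scores_give_half(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.ones(4), y).auc == pytest.approx(0.5)

    def test_scores_equal_labels(self):
        y = np.array([0, 1, 0, 1])
        assert roc_auc(y.astype(float), y).auc == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.normal(size=150)
        y = (rng.random(150) < 0.4).astype(int)
        y[0], y[1] = 0, 1        # both classes guaranteed
        pos, neg = scores[y == 1], scores[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum() \
            + 0.5 * (pos[:, None] == neg[None, :]).sum()
        oracle = wins / (len(pos) * len(neg))
        assert roc_auc(scores, y).auc == pytest.approx(oracle, abs=1e-12)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.zeros(4))


class TestPredictionTimecourse:
    def test_zero_coefficients_flat_probability(self):
        from crossarea.behavior import DetectorModel
        model = DetectorModel(coef=np.zeros(1), intercept=0.3,
                              channels=("M1",))
        starts = 10.0 + 20.0 * np.arange(4)
        trials = ca.make_trial_table(starts - 3.0, starts, starts + 0.2)
        traj = {i: (rs + np.arange(-2.5, 1.0, 0.1) + 0.05,
                    np.random.default_rng(i).normal(size=35))
                for i, rs in enumerate(starts)}
        probs, summary = prediction_timecourse(model, trials, traj)
        expected = 1.0 / (1.0 + np.exp(-0.3))
        for p in probs.values():
            np.testing.assert_allclose(p, expected)
        assert summary == pytest.approx(0.0, abs=1e-12)

    def test_probabilities_bounded(self, small_fit):
        session, _, fit = small_fit
        traj = ca.pipeline.cs_trajectories(session, fit.model)
        X, y, _ = label_detection_samples(session.trials, traj)
        model, _ = fit_reach_detector(X, y)
        probs, _ = prediction_timecourse(model, session.trials, traj)
        for p in probs.values():
            assert np.all((p > 0) & (p < 1))


class TestMedianSeparability:
    def test_identical_distributions(self, rng):
        x = rng.normal(size=100)
        assert median_separability(x, x) == 0.0

    def test_unit_shift(self, rng):
        x = rng.normal(size=101)
        assert median_separability(x, x + 1.0) == pytest.approx(1.0)

    def test_monotone_in_shared_amplitude(self):
        seps = []
        for stage in ("early", "late"):
            cfg = ca.SyntheticConfig(n_units={"M2": 15, "M1": 15},
                                     n_trials=60, seed=31)
            session, _ = ca.generate_session(cfg, stage)
            fit = ca.pipeline.fit_session(session, n_shuffles=40, seed=0)
            traj = ca.pipeline.cs_trajectories(session, fit.model,
                                               regions=("M1",))
            X, y, _ = label_detection_samples(session.trials, traj)
            seps.append(median_separability(X[y == 0, 0], X[y == 1, 0]))
        assert seps[1] > seps[0]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_separability(np.array([]), np.array([1.0]))
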