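"""Calibration tests: relative RMSE, the c sweep, replicate variability and
the held-out colony evaluation."""

import numpy as np
import pytest
from sklearn.base import clone

from antforage import (
    FeedbackCalibrator,
    FeedbackParams,
    SlotSeries,
    SyntheticTrialSpec,
    gen_paired_trial,
    heldout_colony_c,
    relative_rmse,
    replicate_rmse,
    sweep_c,
)
from antforage.calibration import score_batch


class TestRelativeRMSE:
    def test_identical_series_zero(self, flat_series):
        assert relative_rmse(flat_series, flat_series) == 0.0

    def test_constant_offset(self):
        obs = SlotSeries(np.full(10, 2.0))
        sim = SlotSeries(np.full(10, 3.0))
        assert relative_rmse(sim, obs) == pytest.approx(0.5)

    def test_hand_computed_pair(self):
        # diffs (-1,0,1,0,1,2): MSE 7/6, RMSE sqrt(7/6), observed mean 3
        sim = np.array([1, 2, 3, 4, 5, 6], float)
        obs = np.array([2, 2, 2, 4, 4, 4], float)
        assert relative_rmse(sim, obs) == pytest.approx(np.sqrt(7 / 6) / 3)

    def test_offset_scaling_matches_formula(self):
        rng = np.random.default_rng(1)
        obs = rng.poisson(3.0, 50).astype(float) + 1
        for k in (0.5, 2.0):
            assert relative_rmse(obs + k, obs) == pytest.approx(k / obs.mean())

    def test_zero_observed_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_rmse(np.ones(5), np.zeros(5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_rmse(np.ones(5), np.ones(6))


class TestScoreBatch:
    def test_identical_series_zero_under_all_scorings(self):
        obs = np.random.default_rng(2).poisson(1.0, 1100).astype(float) + 0.1
        stack = np.tile(obs, (3, 1))
        for scoring in ("slots", "smoothed", "segments"):
            np.testing.assert_allclose(
                score_batch(stack, obs, scoring=scoring), 0.0, atol=1e-12
            )

    def test_unknown_scoring_rejected(self):
        with pytest.raises(ValueError):
            score_batch(np.ones((1, 10)), np.ones(10), scoring="nope")


class TestSweep:
    def test_single_candidate_grid(self, small_trial, params):
        fr = sweep_c(small_trial, params, c_grid=[0.07], n_iterations=5, seed=0)
        assert fr.best_c == 0.07
        assert fr.c_grid.size == 1

    def test_expectation_self_consistency(self):
        # observed outgoing generated by the deterministic model at c=0.05:
        # a deterministic sweep must hit it exactly with zero error there
        spec = SyntheticTrialSpec(
            return_rate=0.8, true_params=FeedbackParams(c=0.05), seed=3
        )
        trial = gen_paired_trial(spec, mode="expectation")
        fr = sweep_c(trial, FeedbackParams(c=0.0), mode="expectation")
        assert fr.best_c == pytest.approx(0.05)
        assert fr.mean_rmse_per_c.min() == pytest.approx(0.0, abs=1e-12)

    def test_stochastic_recovery_single_trial(self):
        spec = SyntheticTrialSpec(
            return_rate=1.0, true_params=FeedbackParams(c=0.12), seed=21
        )
        trial = gen_paired_trial(spec)
        fr = sweep_c(trial, FeedbackParams(c=0.0), n_iterations=200, seed=22)
        assert abs(fr.best_c - 0.12) <= 0.02

    def test_curve_and_result_invariants(self, small_trial, params):
        fr = sweep_c(small_trial, params, n_iterations=10, seed=5)
        assert fr.best_c in fr.c_grid
        assert np.all(fr.mean_rmse_per_c >= 0)
        assert fr.mean_rmse_per_c.size == fr.c_grid.size

    def test_sweep_reproducible(self, small_trial, params):
        a = sweep_c(small_trial, params, n_iterations=20, seed=9)
        b = sweep_c(small_trial, params, n_iterations=20, seed=9)
        np.testing.assert_array_equal(a.mean_rmse_per_c, b.mean_rmse_per_c)


class TestCalibratorEstimatorAPI:
    def test_get_set_params_clone(self):
        cal = FeedbackCalibrator(n_iterations=17, random_state=3, scoring="slots")
        cal2 = clone(cal)
        assert cal2.get_params()["n_iterations"] == 17
        cal2.set_params(scoring="smoothed")
        assert cal2.scoring == "smoothed"
        assert cal.scoring == "slots"

    def test_fit_predict_sample(self, small_trial):
        cal = FeedbackCalibrator(n_iterations=20, random_state=1)
        cal.fit(small_trial.returning, small_trial.outgoing)
        assert hasattr(cal, "best_c_")
        pred = cal.predict(small_trial.returning)
        assert pred.shape == small_trial.outgoing.counts.shape
        s1 = cal.sample(small_trial.returning, seed=4)
        s2 = cal.sample(small_trial.returning, seed=4)
        np.testing.assert_array_equal(s1, s2)

    def test_mismatched_lengths_rejected(self):
        cal = FeedbackCalibrator()
        with pytest.raises(ValueError):
            cal.fit(np.ones(10), np.ones(11))


class TestReplicateRMSE:
    def test_expectation_mode_replicates_identical(self, params):
        rep = replicate_rmse(SlotSeries(np.ones(100)), params, n_repeats=5,
                             mode="expectation")
        assert np.all(rep.values == 0)

    def test_single_repeat_returns_two_values(self, params, rng):
        arrivals = SlotSeries(rng.poisson(0.8, 500).astype(float))
        rep = replicate_rmse(arrivals, params, n_repeats=1, seed=0)
        assert rep.values.size == 2

    def test_noisier_at_low_rates(self, params):
        rng = np.random.default_rng(13)
        low = SlotSeries(rng.poisson(0.1, 1100).astype(float))
        high = SlotSeries(rng.poisson(1.2, 1100).astype(float))
        rep_low = replicate_rmse(low, params, n_repeats=50, seed=1)
        rep_high = replicate_rmse(high, params, n_repeats=50, seed=2)
        assert np.median(rep_low.values) > np.median(rep_high.values)


class TestHeldoutColony:
    def _colony(self, c, seeds, rate=0.8, mode="stochastic"):
        p = FeedbackParams(c=c)
        return [
            gen_paired_trial(
                SyntheticTrialSpec(return_rate=rate, true_params=p, seed=s),
                colony_id="col", trial_id=f"t{s}", mode=mode,
            )
            for s in seeds
        ]

    def test_expectation_identical_trials_zero_rmse(self):
        trials = self._colony(0.06, [7, 7, 7], mode="expectation")
        res = heldout_colony_c({"col": trials}, FeedbackParams(c=0.0),
                               mode="expectation", seed=0)
        assert res.per_colony_c["col"] == pytest.approx(0.06)
        assert res.mean_rmse == pytest.approx(0.0, abs=1e-12)

    def test_small_colony_skipped_with_warning(self, caplog):
        trials = self._colony(0.06, [1, 2])
        with caplog.at_level("WARNING"):
            res = heldout_colony_c({"tiny": trials}, FeedbackParams(c=0.0), seed=0)
        assert "tiny" in res.skipped
        assert np.isnan(res.mean_rmse)

    def test_shared_c_heldout_error_moderate(self):
        trials = self._colony(0.1, [31, 32, 33])
        res = heldout_colony_c(
            {"col": trials}, FeedbackParams(c=0.0), n_iterations=50, seed=5
        )
        # fitted average c near truth, so held-out RMSE stays at the
        # replicate-noise level rather than exploding
        assert abs(res.per_colony_c["col"] - 0.1) <= 0.02
        assert res.mean_rmse < 0.5
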