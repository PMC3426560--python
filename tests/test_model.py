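"""Feedback- and linear-model unit and property tests.

The expectation-mode oracle used here is a literal loop transcription of the
rate recursion, written independently of the simulator's vectorised paths.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antforage import (
    EventTrace,
    FeedbackParams,
    LinearParams,
    SlotSeries,
    simulate_feedback,
    simulate_linear,
    step_alpha,
)
from antforage.model import simulate_feedback_batch


def oracle_alpha_series(arrivals, departures, p: FeedbackParams):
    """Brute-force recursion: alpha_n from given per-slot departures."""
    alpha, prev_a, prev_d = [], 0.0, 0.0
    for a in arrivals:
        prev_a = max(prev_a - p.q * prev_d + p.c * a - p.d, p.alpha_floor)
        alpha.append(prev_a)
        prev_d = departures.pop(0) if departures else prev_a
    return alpha


class TestStepAlpha:
    @pytest.mark.parametrize(
        "prev_alpha, prev_d, arrivals, expected",
        [
            (0.0, 0, 3, 0.3),            # plain increment, floor not binding
            (0.02, 1, 0, 0.01),          # depletion pushes below the floor
            (0.5, 2, 1, 0.5),            # -0.1 +0.1 balance
        ],
    )
    def test_arithmetic(self, params, prev_alpha, prev_d, arrivals, expected):
        assert step_alpha(prev_alpha, prev_d, arrivals, params) == pytest.approx(
            expected
        )

    def test_hand_recursion_with_fixed_departures(self, params):
        # A=(2,0,1,0,0), D=(1,1,0,0,0) chained by hand:
        # a1=0.2, a2=0.2-0.05=0.15, a3=0.15-0.05+0.1=0.2, a4=a5=0.2
        arrivals = [2, 0, 1, 0, 0]
        fixed_d = [1, 1, 0, 0, 0]
        alpha, prev_a = [], 0.0
        prev_d = 0
        for a, d in zip(arrivals, [0] + fixed_d[:-1]):
            prev_a = step_alpha(prev_a, d, a, params)
            alpha.append(prev_a)
        assert alpha == pytest.approx([0.2, 0.15, 0.2, 0.2, 0.2])

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            step_alpha(-0.1, 0, 0, params)
        with pytest.raises(ValueError):
            step_alpha(0.1, -1, 0, params)
        with pytest.raises(ValueError):
            step_alpha(0.1, 0, -2, params)


class TestSimulateFeedback:
    def test_zero_arrivals_expectation_pins_to_floor(self, params):
        res = simulate_feedback(np.zeros(50), params, mode="expectation")
        assert np.all(res.alpha_series == params.alpha_floor)
        assert np.all(res.departures.counts == params.alpha_floor)

    def test_zero_arrivals_stochastic_rate(self, params):
        n = 10_000
        res = simulate_feedback(np.zeros(n), params, seed=3)
        rate = res.departures.counts.sum() / n
        se = np.sqrt(params.alpha_floor / n)
        assert abs(rate - params.alpha_floor) < 3 * se

    def test_expectation_matches_oracle(self, params):
        rng = np.random.default_rng(5)
        for _ in range(100):
            arrivals = rng.poisson(0.7, size=rng.integers(1, 30)).tolist()
            res = simulate_feedback(np.array(arrivals, float), params,
                                    mode="expectation")
            expected = oracle_alpha_series(arrivals, [], params)
            np.testing.assert_allclose(res.alpha_series, expected, rtol=0, atol=0)
            np.testing.assert_allclose(res.departures.counts, expected)

    def test_empty_arrivals(self, params):
        res = simulate_feedback(np.empty(0), params)
        assert len(res.departures) == 0

    def test_non_integer_arrivals_rejected_in_stochastic_mode(self, params):
        with pytest.raises(ValueError):
            simulate_feedback(np.array([0.5, 1.0]), params, seed=0)

    def test_reproducible_bit_for_bit(self, params):
        arrivals = np.random.default_rng(1).poisson(0.8, 500)
        a = simulate_feedback(arrivals, params, seed=42)
        b = simulate_feedback(arrivals, params, seed=42)
        np.testing.assert_array_equal(a.departures.counts, b.departures.counts)
        np.testing.assert_array_equal(a.alpha_series, b.alpha_series)
        c = simulate_feedback(arrivals, params, seed=43)
        assert not np.array_equal(a.departures.counts, c.departures.counts)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 5), min_size=1, max_size=40),
        c=st.floats(0.0, 0.3),
        q=st.floats(0.0, 0.2),
        d=st.floats(0.0, 0.05),
        seed=st.integers(0, 2**20),
    )
    def test_floor_invariant(self, counts, c, q, d, seed):
        p = FeedbackParams(c=c, q=q, d=d, alpha_floor=0.01)
        res = simulate_feedback(np.array(counts, float), p, seed=seed)
        assert np.all(res.alpha_series >= p.alpha_floor)

    def test_mean_departures_nondecreasing_in_c(self):
        arrivals = np.random.default_rng(2).poisson(0.8, 400)
        rng = np.random.default_rng(7)
        means = []
        for c in (0.02, 0.1, 0.25):
            p = FeedbackParams(c=c)
            deps = simulate_feedback_batch(arrivals, p, np.array([c]), 200, rng)[0]
            means.append(deps.sum(axis=1).mean())
        assert means[0] <= means[1] <= means[2]

    def test_batch_mean_tracks_expectation(self, params):
        arrivals = np.random.default_rng(3).poisson(0.8, 300)
        rng = np.random.default_rng(9)
        deps = simulate_feedback_batch(arrivals, params, np.array([params.c]),
                                       500, rng)[0]
        exp = simulate_feedback(arrivals, params, mode="expectation")
        # slot-wise means of stochastic runs follow the deterministic trajectory
        assert abs(deps.mean() - exp.departures.counts.mean()) < 0.05

    def test_slot_series_input_keeps_slot_duration(self, params):
        s = SlotSeries(np.zeros(10), slot_duration=2.0)
        res = simulate_feedback(s, params, seed=0)
        assert res.departures.slot_duration == 2.0


class TestSimulateLinear:
    def test_all_zero_when_no_input_and_no_baseline(self):
        trace = EventTrace(np.empty(0))
        p = LinearParams(lambda_b=0.0, lambda_ac=0.3, tau=10.0)
        out = simulate_linear(trace, p, horizon=100, step=1.0, seed=0)
        assert np.all(out.counts == 0)

    def test_baseline_rate_recovered(self):
        trace = EventTrace(np.empty(0))
        p = LinearParams(lambda_b=0.5, lambda_ac=0.0, tau=5.0)
        out = simulate_linear(trace, p, horizon=20_000, step=1.0, seed=1)
        se = np.sqrt(0.5 / 20_000)
        assert abs(out.mean_rate - 0.5) < 3 * se

    def test_burst_drives_expected_rate(self):
        # k=5 returns at t=10; while the burst is inside the window (t-tau, t]
        # each step's expected count is lambda_ac * k * step
        k, lam_ac, tau = 5, 0.2, 50.0
        trace = EventTrace(np.full(k, 10.0))
        p = LinearParams(lambda_b=0.0, lambda_ac=lam_ac, tau=tau)
        totals = []
        for seed in range(300):
            out = simulate_linear(trace, p, horizon=60, step=1.0, seed=seed)
            totals.append(out.counts[10:60])  # steps t=11..60 contain the burst
        m = np.mean(totals)
        se = np.sqrt(lam_ac * k / (300 * 50))
        assert abs(m - lam_ac * k) < 3 * se

    def test_unsorted_events_rejected(self):
        trace = EventTrace.__new__(EventTrace)  # bypass ctor validation
        object.__setattr__(trace, "times", np.array([3.0, 1.0]))
        object.__setattr__(trace, "direction", "returning")
        object.__setattr__(trace, "frame_rate", 30.0)
        p = LinearParams(lambda_b=0.0, lambda_ac=0.1, tau=5.0)
        with pytest.raises(ValueError):
            simulate_linear(trace, p, horizon=10, step=1.0)

    def test_tau_longer_than_horizon_rejected(self):
        p = LinearParams(lambda_b=0.0, lambda_ac=0.1, tau=50.0)
        with pytest.raises(ValueError):
            simulate_linear(EventTrace(np.empty(0)), p, horizon=10, step=1.0)
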