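"""Generative models of outgoing-forager traffic.

Two models are implemented. The linear model makes the outgoing rate a
baseline plus a term proportional to the number of returns in a recent
window tau. The feedback model operates in discrete time slots: the
departure rate alpha_n rises by c per returning forager, falls by q per
departure (each departure empties a place in the entrance-tunnel queue),
decays by d per slot, and never drops below a floor. Departures in slot n
are Poisson(alpha_n), independent across slots given the rates.

Arrivals are taken to occur at the start of a slot, departures at the end,
so the arrivals of slot n influence its own departures while the departures
of slot n-1 influence alpha_n.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .structures import EventTrace, FeedbackParams, LinearParams, SimResult, SlotSeries

__all__ = [
    "step_alpha",
    "simulate_feedback",
    "simulate_feedback_batch",
    "simulate_linear",
]


def step_alpha(
    prev_alpha: float,
    prev_departures: float,
    arrivals: float,
    params: FeedbackParams,
) -> float:
    """One update of the departure rate.

    alpha_n = max(alpha_{n-1} - q*D_{n-1} + c*A_n - d, alpha_floor)

    Deterministic; the stochasticity of the model lives entirely in the
    Poisson departure draws.
    """
    if prev_alpha < 0:
        raise ValueError("prev_alpha must be non-negative")
    if prev_departures < 0 or arrivals < 0:
        raise ValueError("counts must be non-negative")
    return max(
        prev_alpha - params.q * prev_departures + params.c * arrivals - params.d,
        params.alpha_floor,
    )


def simulate_feedback(
    arrivals: Union[SlotSeries, np.ndarray],
    params: FeedbackParams,
    seed: Optional[int] = None,
    mode: str = "stochastic",
) -> SimResult:
    """Run the feedback model over a returning-forager slot series.

    Parameters
    ----------
    arrivals : SlotSeries or array-like
        Returning foragers per slot (A_n). Must be integral in stochastic
        mode.
    params : FeedbackParams
    seed : int, optional
        Seed for the Poisson departure draws (stochastic mode only).
    mode : {"stochastic", "expectation"}
        Stochastic mode draws D_n ~ Poisson(alpha_n). Expectation mode sets
        D_n = alpha_n (real-valued), giving a deterministic trajectory used
        as a test oracle and for noise-free self-consistency checks.

    Returns
    -------
    SimResult
        Per-slot rates alpha_n (all >= alpha_floor) and departures D_n.
    """
    if mode not in ("stochastic", "expectation"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(arrivals, SlotSeries):
        slot_duration = arrivals.slot_duration
        a = (
            arrivals.require_integer().astype(float)
            if mode == "stochastic"
            else arrivals.counts
        )
    else:
        slot_duration = params.slot_duration
        a = np.asarray(arrivals, dtype=float)
        if mode == "stochastic" and not np.allclose(a, np.round(a)):
            raise ValueError("arrival counts must be integral in stochastic mode")
    n = a.size
    if n == 0:
        return SimResult(np.empty(0), SlotSeries(np.empty(0), slot_duration), seed)

    rng = np.random.default_rng(seed)
    alpha = np.empty(n)
    departures = np.empty(n)
    prev_alpha = 0.0  # alpha_0; the floor applies from slot 1 onward
    prev_d = 0.0
    for i in range(n):
        prev_alpha = step_alpha(prev_alpha, prev_d, a[i], params)
        alpha[i] = prev_alpha
        if mode == "stochastic":
            prev_d = float(rng.poisson(prev_alpha))
        else:
            prev_d = prev_alpha
        departures[i] = prev_d
    return SimResult(alpha, SlotSeries(departures, slot_duration), seed)


def simulate_feedback_batch(
    arrivals: Union[SlotSeries, np.ndarray],
    params: FeedbackParams,
    c_values: np.ndarray,
    n_iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised stochastic runs over a grid of c values.

    Simulates ``n_iterations`` independent stochastic trajectories for each
    candidate c (q, d, floor and the arrivals held fixed), stepping all
    chains through the slots together.

    Returns
    -------
    ndarray of shape (len(c_values), n_iterations, n_slots)
        Departure counts per chain and slot.
    """
    if isinstance(arrivals, SlotSeries):
        a = arrivals.require_integer().astype(float)
    else:
        a = np.asarray(arrivals, dtype=float)
    c = np.asarray(c_values, dtype=float).reshape(-1, 1)
    n = a.size
    out = np.empty((c.shape[0], n_iterations, n), dtype=np.int64)
    alpha = np.zeros((c.shape[0], n_iterations))
    prev_d = np.zeros_like(alpha)
    for i in range(n):
        alpha = np.maximum(
            alpha - params.q * prev_d + c * a[i] - params.d, params.alpha_floor
        )
        prev_d = rng.poisson(alpha).astype(float)
        out[:, :, i] = prev_d
    return out


def simulate_linear(
    return_events: EventTrace,
    params: LinearParams,
    horizon: float,
    step: float,
    seed: Optional[int] = None,
) -> SlotSeries:
    """Run the linear rate model against a returning-forager event trace.

    For each step endpoint t, the outgoing count is drawn as
    Poisson(lambda_b * step) + Poisson(lambda(t) * step) with
    lambda(t) = lambda_ac * f(t, tau), where f counts returning events in
    the half-open window (t - tau, t]. Rates are per second.
    """
    if params.tau > horizon:
        raise ValueError("tau must not exceed the horizon")
    if step <= 0:
        raise ValueError("step must be positive")
    times = return_events.times
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("return events must be sorted ascending")
    t = np.arange(step, horizon + step / 2, step)
    f = np.searchsorted(times, t, side="right") - np.searchsorted(
        times, t - params.tau, side="right"
    )
    lam = params.lambda_ac * f
    rng = np.random.default_rng(seed)
    counts = rng.poisson(params.lambda_b * step, size=t.size) + rng.poisson(lam * step)
    return SlotSeries(counts, slot_duration=step)
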