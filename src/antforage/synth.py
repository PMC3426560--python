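"""Synthetic field-like data: Poisson return streams, removal trials, and
paired trials generated by the feedback model with known parameters.

The generators reproduce the statistical structure the analyses assume —
homogeneous Poisson returning-forager streams at field-realistic rates
(0.1-1.2 ants/sec), the removal design (returns suppressed mid-trial, then
resuming), and outgoing series produced by the model itself — so parameter
recovery and every diagnostic can be exercised end-to-end without field
recordings. An optional observation-noise model roughens the "observed"
outgoing series the way real counts are rough; it is a construction of this
package, not part of the behavioural model, and is labelled as such in
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .model import simulate_feedback
from .structures import (
    EventTrace,
    FeedbackParams,
    RETURNING,
    SlotSeries,
    TrialDesign,
    TrialRecord,
)
from .traces import bin_events

__all__ = [
    "SyntheticTrialSpec",
    "gen_poisson_returns",
    "gen_removal_trial",
    "gen_paired_trial",
    "gen_trial_ensemble",
]

DEFAULT_NOISE_MAGNITUDE = 0.5  # per-slot Poisson-difference noise intensity


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Recipe for one synthetic removal trial.

    ``return_rate`` is the homogeneous returning-forager rate in ants/sec
    (field range 0.1-1.2). ``observation_noise`` is the intensity m of the
    mean-zero per-slot count noise added to the outgoing series when
    emulating imperfect observation: each slot gains Poisson(m) - Poisson(m)
    counts (clipped at zero). 0 disables it.
    """

    return_rate: float
    design: TrialDesign = field(default_factory=TrialDesign)
    true_params: Optional[FeedbackParams] = None
    observation_noise: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.return_rate <= 0:
            raise ValueError("return_rate must be positive")
        if self.observation_noise < 0:
            raise ValueError("observation_noise must be non-negative")


def gen_poisson_returns(
    rate: float,
    span: tuple[float, float],
    seed: Union[int, np.random.Generator, None] = None,
) -> EventTrace:
    """Homogeneous Poisson event stream on a span (i.i.d. exponential gaps)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    start, end = span
    if end <= start:
        return EventTrace(np.empty(0), RETURNING)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # draw gaps in blocks until the span is covered
    expected = int(np.clip(rate * (end - start) * 1.5, 16, 1_000_000))
    times: list[np.ndarray] = []
    t = start
    while t < end:
        gaps = rng.exponential(1.0 / rate, size=expected)
        block = t + np.cumsum(gaps)
        times.append(block)
        t = block[-1]
    all_times = np.concatenate(times)
    return EventTrace(all_times[all_times < end], RETURNING)


def gen_removal_trial(spec: SyntheticTrialSpec) -> EventTrace:
    """Returning-forager stream for a removal trial.

    Poisson returns at the spec rate during the pre and post windows; no
    returns during the removal window or the travel gap before the post
    window; resumption is instantaneous at the post-window start (any lag in
    the colony's response is a property of the outgoing side, not imposed
    here).
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.design
    pre = gen_poisson_returns(spec.return_rate, (d.pre_window[0], d.removal_window[0]), rng)
    post = gen_poisson_returns(spec.return_rate, (d.post_window[0], d.post_window[1]), rng)
    return EventTrace(np.concatenate([pre.times, post.times]), RETURNING)


def _observation_noise(
    counts: np.ndarray, magnitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean-zero per-slot displacement: Poisson(m) - Poisson(m), clipped at 0."""
    noise = rng.poisson(magnitude, counts.size) - rng.poisson(magnitude, counts.size)
    return np.maximum(counts + noise, 0)


def gen_paired_trial(
    spec: SyntheticTrialSpec,
    colony_id: str = "synthetic",
    year: str = "0",
    trial_id: str = "",
    mode: str = "stochastic",
) -> TrialRecord:
    """Paired returning/outgoing trial with known ground truth.

    The returning trace comes from :func:`gen_removal_trial`; the outgoing
    series from the feedback model under ``spec.true_params`` (stochastic by
    default; expectation mode gives the deterministic trajectory). When
    ``spec.observation_noise`` > 0 the outgoing series is additionally
    perturbed by the synthetic observation-noise model. The true c is
    recorded in ``meta`` for recovery scoring.
    """
    if spec.true_params is None:
        raise ValueError("spec.true_params is required for paired generation")
    params = spec.true_params
    ss = np.random.SeedSequence(spec.seed)
    s_ret, s_sim, s_noise = ss.spawn(3)
    ret_spec = SyntheticTrialSpec(
        spec.return_rate, spec.design, params, 0.0,
        int(s_ret.generate_state(1)[0] % (2**31)),
    )
    returning_trace = gen_removal_trial(ret_spec)
    returning = bin_events(returning_trace, params.slot_duration, spec.design.span)
    sim = simulate_feedback(
        returning, params,
        seed=int(s_sim.generate_state(1)[0] % (2**31)),
        mode=mode,
    )
    out_counts = sim.departures.counts
    if spec.observation_noise > 0:
        if mode != "stochastic":
            raise ValueError("observation noise requires stochastic mode")
        out_counts = _observation_noise(
            out_counts, spec.observation_noise, np.random.default_rng(s_noise)
        )
    return TrialRecord(
        colony_id=colony_id,
        year=year,
        returning=returning,
        outgoing=SlotSeries(out_counts, params.slot_duration),
        design=spec.design,
        trial_id=trial_id or f"{colony_id}-r{spec.return_rate:g}",
        meta={
            "true_c": params.c,
            "return_rate": spec.return_rate,
            "observation_noise": spec.observation_noise,
            "seed": spec.seed,
            "synthetic": True,
        },
    )


def gen_trial_ensemble(
    rates: Sequence[float],
    params: FeedbackParams,
    design: Optional[TrialDesign] = None,
    observation_noise: float = 0.0,
    seed: Optional[int] = None,
    mode: str = "stochastic",
) -> list[TrialRecord]:
    """One paired trial per requested return rate, from a single master seed."""
    design = design or TrialDesign()
    ss = np.random.SeedSequence(seed)
    trials = []
    for i, (rate, child) in enumerate(zip(rates, ss.spawn(len(rates)))):
        spec = SyntheticTrialSpec(
            return_rate=rate,
            design=design,
            true_params=params,
            observation_noise=observation_noise,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        trials.append(
            gen_paired_trial(spec, colony_id=f"synthetic-{i:02d}", trial_id=f"trial-{i:02d}", mode=mode)
        )
    return trials
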