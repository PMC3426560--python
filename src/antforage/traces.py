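"""Trial segmentation, binning, smoothing and correlation statistics.

The correlation analysis asks how tightly the outgoing-forager rate tracks
the returning-forager rate: both traces are smoothed with a moving-average
(rect/boxcar) filter and their Pearson correlation is taken per trial.
Across trials, a Spearman rank test checks whether the correlation rises
with the trial's mean return rate, and a paired t-test compares the
simulated-vs-returning correlations with the observed-vs-returning ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .model import simulate_feedback
from .structures import (
    EventTrace,
    FeedbackParams,
    RETURNING,
    SlotSeries,
    TrialDesign,
    TrialRecord,
)

__all__ = [
    "CorrelationRecord",
    "TrendTest",
    "PairedTTest",
    "bin_events",
    "apply_travel_offset",
    "rect_smooth",
    "trace_correlation",
    "rate_trend_test",
    "compare_correlations",
    "build_correlation_record",
    "segment_counts",
]

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_RADIUS = 25  # slots


@dataclass(frozen=True)
class CorrelationRecord:
    """Per-trial correlation summary (one point of the rate-vs-correlation
    scatter)."""

    trial_id: str
    mean_return_rate: float
    r_observed: float
    r_simulated: float


@dataclass(frozen=True)
class TrendTest:
    """Spearman rank-correlation trend with normal-approximation z and p."""

    rho: float
    z: float
    p: float
    n: int


@dataclass(frozen=True)
class PairedTTest:
    t: float
    p: float
    n: int
    degenerate: bool = False


def bin_events(
    trace: EventTrace, slot_duration: float, span: tuple[float, float]
) -> SlotSeries:
    """Count events per half-open slot [k*dt, (k+1)*dt) over the span."""
    if slot_duration <= 0:
        raise ValueError("slot_duration must be positive")
    start, end = span
    if end <= start:
        raise ValueError("span must have positive length")
    n_slots = int(np.ceil((end - start) / slot_duration - 1e-12))
    t = trace.times
    t = t[(t >= start) & (t < end)]
    idx = np.floor((t - start) / slot_duration).astype(np.int64)
    idx = np.clip(idx, 0, n_slots - 1)  # guard float round-off at the end edge
    counts = np.bincount(idx, minlength=n_slots)
    return SlotSeries(counts, slot_duration)


def apply_travel_offset(trace: EventTrace, design: TrialDesign) -> EventTrace:
    """Align trail-crossing times with nest-entrance times.

    Returning timestamps are shifted forward by the travel time (the ant
    still has to walk from the camera to the nest); outgoing timestamps are
    shifted back. Events landing outside the trial span are dropped and the
    drop count logged.
    """
    offset = design.travel_time if trace.direction == RETURNING else -design.travel_time
    times = trace.times + offset
    lo, hi = design.span
    keep = (times >= lo) & (times <= hi)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "apply_travel_offset: dropped %d %s event(s) shifted outside %s",
            dropped, trace.direction, design.span,
        )
    return EventTrace(times[keep], trace.direction, trace.frame_rate)


def rect_smooth(
    series: Union[SlotSeries, np.ndarray], radius: int
) -> np.ndarray:
    """Moving-average (rect/boxcar) filter of the given radius.

    Each value becomes the mean over slots [i - radius, i + radius]; the
    window is truncated at the series boundaries rather than padded, so no
    invented data enter at the edges. Radius 0 is the identity. For a
    multi-dimensional input the filter runs along the last axis.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    x = series.counts if isinstance(series, SlotSeries) else np.asarray(series, float)
    n = x.shape[-1]
    if n == 0 or radius == 0:
        return x.astype(float)
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1, dtype=float)], axis=-1
    )
    i = np.arange(n)
    lo = np.maximum(i - radius, 0)
    hi = np.minimum(i + radius + 1, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def trace_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two (smoothed) series.

    NaN with a warning when either input is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 slots for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def segment_counts(
    series: SlotSeries, design: TrialDesign
) -> dict[str, np.ndarray]:
    """Slice a slot series into the pre/removal/post segments.

    The gap between removal end and post-window start (430-500 s by
    default, the time ants filmed on the trail need to reach the nest) is
    excluded from every segment.
    """
    dt = series.slot_duration
    out = {}
    for name, (lo, hi) in (
        ("pre", design.pre_window),
        ("removal", design.removal_window),
        ("post", design.post_window),
    ):
        i0 = int(np.ceil(lo / dt - 1e-12))
        i1 = int(np.floor(hi / dt + 1e-12))
        out[name] = series.counts[i0:min(i1, len(series))]
    return out


def rate_trend_test(
    records: Sequence[CorrelationRecord], which: str = "simulated"
) -> TrendTest:
    """Does the per-trial correlation rise with the mean return rate?

    Spearman rank correlation (midranks for ties) between each trial's mean
    returning rate and its chosen correlation column, with the
    normal-approximation z = rho * sqrt(n - 1) and a two-sided p.
    """
    if which not in ("observed", "simulated"):
        raise ValueError("which must be 'observed' or 'simulated'")
    if len(records) < 5:
        raise ValueError("need at least 5 records for a trend test")
    x = np.array([r.mean_return_rate for r in records])
    y = np.array(
        [r.r_simulated if which == "simulated" else r.r_observed for r in records]
    )
    rho = float(stats.spearmanr(x, y).statistic)
    z = rho * np.sqrt(len(records) - 1)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TrendTest(rho=rho, z=float(z), p=p, n=len(records))


def compare_correlations(records: Sequence[CorrelationRecord]) -> PairedTTest:
    """Paired t-test of r_simulated vs r_observed across trials.

    Positive t means the model's outgoing trace tracks the returning trace
    more tightly than the observed outgoing trace does. A zero-variance
    difference with nonzero mean is degenerate (t unbounded) and flagged.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a paired t-test")
    sim = np.array([r.r_simulated for r in records])
    obs = np.array([r.r_observed for r in records])
    diff = sim - obs
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return PairedTTest(t=0.0, p=1.0, n=len(records))
        return PairedTTest(
            t=float(np.inf) * np.sign(diff[0]), p=0.0, n=len(records), degenerate=True
        )
    res = stats.ttest_rel(sim, obs)
    return PairedTTest(t=float(res.statistic), p=float(res.pvalue), n=len(records))


def build_correlation_record(
    trial: TrialRecord,
    params: FeedbackParams,
    radius: int = DEFAULT_SMOOTH_RADIUS,
    seed: Optional[int] = None,
) -> CorrelationRecord:
    """Compute one trial's correlation pair.

    r_observed correlates the smoothed returning series with the smoothed
    observed outgoing series; r_simulated correlates the same smoothed
    returning series with a fresh model simulation driven by it (at the
    supplied parameters, typically the fitted c).
    """
    ret_s = rect_smooth(trial.returning, radius)
    obs_s = rect_smooth(trial.outgoing, radius)
    sim = simulate_feedback(trial.returning, params, seed=seed)
    sim_s = rect_smooth(sim.departures, radius)
    return CorrelationRecord(
        trial_id=trial.trial_id,
        mean_return_rate=trial.returning.mean_rate,
        r_observed=trace_correlation(ret_s, obs_s),
        r_simulated=trace_correlation(ret_s, sim_s),
    )
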