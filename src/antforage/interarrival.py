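"""Poisson-process diagnostics for returning-forager event streams.

Under a homogeneous Poisson process the gaps between successive returns are
i.i.d. exponential and independent of the preceding gap. The diagnostic
fits an exponential to the empirical interarrival distribution by maximum
likelihood (rate = 1/mean), scores the fit by total variation distance on a
common discretisation, and checks lag-1 independence by the sample
correlation of successive gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .structures import EventTrace

__all__ = [
    "PoissonFitReport",
    "interarrivals",
    "fit_exponential",
    "tv_distance",
    "lag1_independence",
    "poisson_fit_report",
]


@dataclass(frozen=True)
class PoissonFitReport:
    """Summary of the exponential-interarrival fit for one trace.

    ``rate`` is in events per unit of the input timestamps (per second for
    second-resolved traces, per frame for frame-resolved ones).
    """

    rate: float
    tv_error: float
    n_intervals: int
    lag1_correlation: float


def interarrivals(trace: Union[EventTrace, np.ndarray]) -> np.ndarray:
    """Gaps between successive events; length = n_events - 1."""
    times = trace.times if isinstance(trace, EventTrace) else np.asarray(trace, float)
    if times.size < 2:
        raise ValueError("need at least 2 events to form interarrival times")
    return np.diff(times)


def fit_exponential(durations: np.ndarray) -> float:
    """Maximum-likelihood exponential rate: the reciprocal mean duration."""
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 durations")
    mean = durations.mean()
    if mean <= 0:
        raise ValueError("mean duration must be positive to fit a rate")
    return 1.0 / mean


def _tv(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two discrete mass vectors."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def tv_distance(
    durations: np.ndarray, rate: float, bin_width: float = 1.0
) -> float:
    """Total variation distance between empirical durations and an
    exponential fit, both discretised to bins of ``bin_width``.

    Bins are [0, w), [w, 2w), ... up to the largest duration, plus an
    open-ended tail bin that absorbs the remaining exponential mass.
    Bounded in [0, 1]: 0 for a perfect match, 1 for disjoint supports.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("durations must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    n_bins = max(int(np.ceil((durations.max() + 1e-12) / bin_width)), 1)
    edges = bin_width * np.arange(n_bins + 1)
    emp, _ = np.histogram(durations, bins=edges)
    p = emp / durations.size
    cdf = stats.expon.cdf(edges, scale=1.0 / rate)
    q = np.diff(cdf)
    tail = stats.expon.sf(edges[-1], scale=1.0 / rate)  # open-ended bin; p there is 0
    return _tv(np.append(p, 0.0), np.append(q, tail))


def lag1_independence(durations: np.ndarray) -> float:
    """Sample correlation between each gap and the next.

    Near zero for i.i.d. gaps (the Poisson signature); NaN with a warning
    when a series is constant and the correlation is undefined.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 3:
        raise ValueError("need at least 3 durations for a lag-1 correlation")
    x, y = durations[:-1], durations[1:]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant durations: lag-1 correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def poisson_fit_report(
    trace: EventTrace,
    bin_width: float = 1.0,
    window: Optional[tuple[float, float]] = None,
) -> PoissonFitReport:
    """Full Poisson-process diagnostic for one event trace.

    ``window`` restricts the analysis to events with window[0] <= t <
    window[1]; the field protocol used the pre-removal period 60-240 s.
    ``bin_width`` is in the units of the timestamps (1 frame for
    frame-resolved traces).
    """
    times = trace.times
    if window is not None:
        lo, hi = window
        times = times[(times >= lo) & (times < hi)]
    gaps = interarrivals(times)
    rate = fit_exponential(gaps)
    tv = tv_distance(gaps, rate, bin_width=bin_width)
    lag1 = lag1_independence(gaps) if gaps.size >= 3 else float("nan")
    return PoissonFitReport(
        rate=rate, tv_error=tv, n_intervals=int(gaps.size), lag1_correlation=lag1
    )
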