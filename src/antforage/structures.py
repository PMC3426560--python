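"""Core data structures for foraging-trace modelling.

Events are timestamps (seconds) of ants crossing a counting line in one
direction; slot series are per-slot counts at a fixed slot duration. The
feedback model parameters live in :class:`FeedbackParams`; the removal-trial
window layout in :class:`TrialDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

RETURNING = "returning"
OUTGOING = "outgoing"
DIRECTIONS = (RETURNING, OUTGOING)

DEFAULT_FRAME_RATE = 30.0  # frames per second of the field video


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-d sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class EventTrace:
    """Ordered event timestamps for one traffic direction of one trial.

    Parameters
    ----------
    times : array-like of float
        Event timestamps in seconds, weakly ascending (ties allowed:
        simultaneous crossings happen).
    direction : str
        Either ``"returning"`` or ``"outgoing"``.
    frame_rate : float
        Frames per second if the source was frame-resolved video.
    """

    times: np.ndarray
    direction: str = RETURNING
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self):
        times = _as_float_array(self.times)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("event times must be weakly ascending")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "times", times)

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def shifted(self, offset: float) -> "EventTrace":
        return EventTrace(self.times + offset, self.direction, self.frame_rate)


@dataclass(frozen=True)
class SlotSeries:
    """Per-slot counts (arrivals or departures) at a fixed slot duration.

    Counts are non-negative; they are integral for observed/stochastic data
    but may be real-valued when produced by the deterministic
    expectation-mode simulator.
    """

    counts: np.ndarray
    slot_duration: float = 1.0

    def __post_init__(self):
        counts = _as_float_array(self.counts)
        if np.any(counts < 0):
            raise ValueError("slot counts must be non-negative")
        if self.slot_duration <= 0:
            raise ValueError("slot_duration must be positive")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def mean_rate(self) -> float:
        """Mean count per second over the series."""
        if len(self) == 0:
            return 0.0
        return float(self.counts.mean() / self.slot_duration)

    def require_integer(self) -> np.ndarray:
        """Counts as integers; error if any count is non-integral."""
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("slot counts must be integral here")
        return np.round(self.counts).astype(np.int64)


@dataclass(frozen=True)
class FeedbackParams:
    """Constants of the discrete-time feedback model.

    ``alpha_floor`` is the baseline departure rate the colony maintains even
    with no returns (ants per slot); ``c`` the increment to the departure
    rate per returning forager; ``q`` the decrement per departure (queue
    depletion at the tunnel mouth); ``d`` the per-slot decay of
    responsiveness.
    """

    c: float
    q: float = 0.05
    d: float = 0.0
    alpha_floor: float = 0.01
    slot_duration: float = 1.0

    def __post_init__(self):
        if self.alpha_floor <= 0:
            raise ValueError("alpha_floor must be positive")
        if self.c < 0 or self.q < 0 or self.d < 0:
            raise ValueError("c, q, d must be non-negative")
        if self.slot_duration <= 0:
            raise ValueError("slot_duration must be positive")

    def with_c(self, c: float) -> "FeedbackParams":
        return FeedbackParams(c, self.q, self.d, self.alpha_floor, self.slot_duration)


@dataclass(frozen=True)
class LinearParams:
    """Constants of the linear rate model.

    ``lambda_b`` is the baseline outgoing rate (per second); ``lambda_ac``
    the outgoing foragers per returning forager; ``tau`` the window (seconds)
    over which recent returns are integrated.
    """

    lambda_b: float
    lambda_ac: float
    tau: float

    def __post_init__(self):
        if self.lambda_b < 0 or self.lambda_ac < 0:
            raise ValueError("lambda_b and lambda_ac must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class TrialDesign:
    """Window layout of the forager-removal experiment.

    Default windows: pre-removal 0-240 s, removal 240-430 s, post-removal
    500-1100 s. The 430-500 s gap allows ants filmed on the trail to reach
    the nest and is excluded from segment statistics. ``travel_time`` is the
    camera-to-nest transit offset applied to align trail crossings with
    nest-entrance events.
    """

    pre_window: tuple[float, float] = (0.0, 240.0)
    removal_window: tuple[float, float] = (240.0, 430.0)
    post_window: tuple[float, float] = (500.0, 1100.0)
    travel_time: float = 0.0

    def __post_init__(self):
        windows = (self.pre_window, self.removal_window, self.post_window)
        for lo, hi in windows:
            if hi < lo:
                raise ValueError("each window must have start <= end")
        for (_, hi), (lo, _) in zip(windows[:-1], windows[1:]):
            if lo < hi:
                raise ValueError("windows must be ordered and non-overlapping")
        if self.travel_time < 0:
            raise ValueError("travel_time must be non-negative")

    @property
    def span(self) -> tuple[float, float]:
        return (self.pre_window[0], self.post_window[1])

    @property
    def gap_window(self) -> tuple[float, float]:
        """The excluded interval between removal end and post-window start."""
        return (self.removal_window[1], self.post_window[0])


@dataclass(frozen=True)
class SimResult:
    """Output of one feedback-model run: per-slot rates and departures."""

    alpha_series: np.ndarray
    departures: SlotSeries
    seed: Optional[int] = None

    def __post_init__(self):
        alpha = _as_float_array(self.alpha_series)
        if alpha.size != len(self.departures):
            raise ValueError("alpha_series and departures must have equal length")
        object.__setattr__(self, "alpha_series", alpha)


@dataclass
class TrialRecord:
    """One trial: paired returning/outgoing slot series plus design metadata."""

    colony_id: str
    year: str
    returning: SlotSeries
    outgoing: SlotSeries
    design: TrialDesign = field(default_factory=TrialDesign)
    trial_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.returning) != len(self.outgoing):
            raise ValueError("returning and outgoing series must cover the same slots")
        if not self.trial_id:
            self.trial_id = f"{self.colony_id}-{self.year}"
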