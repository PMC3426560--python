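"""Calibration of the feedback model's single free parameter c.

c — the boost each returning forager gives to the departure rate — is fitted
by sweeping a grid of candidates and scoring each by the relative
root-mean-square error between simulated and observed outgoing rates,
averaged over repeated stochastic runs. The other constants (q, d, floor)
are held fixed.

Scoring compares *rates*, i.e. rect-smoothed series (radius 25 slots by
default), not raw per-slot Poisson counts. Raw-count scoring is available
(``scoring="slots"``) but is a biased estimator of c: the per-slot variance
of the simulated departures grows linearly with c, so the expected RMSE is
minimised roughly q/(2 * mean arrival rate) below the true c — two to five
grid steps under field-realistic rates. Smoothing (or comparing
per-segment mean rates, ``scoring="segments"``) suppresses the
count-variance term and makes the sweep recover its own parameter; see
docs/methods.md for the derivation.

Two variability procedures accompany the sweep: the replicate-vs-replicate
RMSE (how much disagreement pure departure randomness produces) and a
held-out evaluation that fits c on part of a colony's trials and scores the
rest with the averaged c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .model import simulate_feedback_batch
from .structures import FeedbackParams, SlotSeries, TrialRecord

__all__ = [
    "FitResult",
    "ReplicateRMSE",
    "HeldoutColonyResult",
    "relative_rmse",
    "score_batch",
    "sweep_c",
    "replicate_rmse",
    "heldout_colony_c",
]

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = np.round(np.arange(0.01, 0.25 + 1e-9, 0.01), 10)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a c sweep: the RMSE-vs-c curve and its argmin."""

    c_grid: np.ndarray
    mean_rmse_per_c: np.ndarray
    best_c: float
    n_iterations: int
    seed: Optional[int] = None


@dataclass(frozen=True)
class ReplicateRMSE:
    """Pairwise relative RMSEs among replicate simulated outgoing traces.

    Per repeat, three traces A, B, C are simulated from the same returning
    series; A vs B and A vs C are scored with A as the reference series.
    """

    rmse_ab: np.ndarray
    rmse_ac: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.rmse_ab, self.rmse_ac])

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class HeldoutColonyResult:
    """Held-out evaluation of colony-averaged c."""

    per_colony_c: dict = field(default_factory=dict)
    per_colony_rmse: dict = field(default_factory=dict)
    skipped: tuple = ()

    @property
    def mean_rmse(self) -> float:
        vals = [v for rs in self.per_colony_rmse.values() for v in rs]
        return float(np.mean(vals)) if vals else float("nan")


def _counts(x: Union[SlotSeries, np.ndarray]) -> np.ndarray:
    return x.counts if isinstance(x, SlotSeries) else np.asarray(x, dtype=float)


def relative_rmse(
    simulated: Union[SlotSeries, np.ndarray], observed: Union[SlotSeries, np.ndarray]
) -> float:
    """RMSE of per-slot differences, normalised by the observed mean.

    Dimensionless; 0 for identical series. Undefined (raises) when the
    observed series has zero mean.
    """
    s, o = _counts(simulated), _counts(observed)
    if s.shape != o.shape:
        raise ValueError("simulated and observed series must have equal length")
    mean_obs = o.mean()
    if mean_obs <= 0:
        raise ValueError("observed series must have positive mean")
    return float(np.sqrt(np.mean((s - o) ** 2)) / mean_obs)


def _batch_relative_rmse(departures: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """relative_rmse for a (..., n_slots) stack of simulated series."""
    mean_obs = observed.mean()
    if mean_obs <= 0:
        raise ValueError("observed series must have positive mean")
    return np.sqrt(np.mean((departures - observed) ** 2, axis=-1)) / mean_obs


DEFAULT_SEGMENT_BOUNDS = ((0.0, 240.0), (240.0, 430.0), (500.0, 1100.0))


def score_batch(
    departures: np.ndarray,
    observed: np.ndarray,
    scoring: str = "smoothed",
    smooth_radius: int = 25,
    slot_duration: float = 1.0,
    segment_bounds: Sequence[tuple[float, float]] = DEFAULT_SEGMENT_BOUNDS,
) -> np.ndarray:
    """Relative RMSE of a (..., n_slots) stack of simulated series.

    scoring="smoothed" rect-smooths both sides before the RMSE (the
    normaliser stays the raw observed mean); "slots" compares raw per-slot
    counts; "segments" compares mean rates over the given second-resolved
    windows (n values per series instead of n_slots).
    """
    from .traces import rect_smooth  # local import; traces imports model only

    observed = np.asarray(observed, dtype=float)
    if scoring == "slots":
        return _batch_relative_rmse(departures, observed)
    if scoring == "smoothed":
        mean_obs = observed.mean()
        if mean_obs <= 0:
            raise ValueError("observed series must have positive mean")
        sim_s = rect_smooth(departures, smooth_radius)
        obs_s = rect_smooth(observed, smooth_radius)
        return np.sqrt(np.mean((sim_s - obs_s) ** 2, axis=-1)) / mean_obs
    if scoring == "segments":
        n = observed.shape[-1]
        sims, obss = [], []
        for lo, hi in segment_bounds:
            i0 = max(int(np.ceil(lo / slot_duration - 1e-12)), 0)
            i1 = min(int(np.floor(hi / slot_duration + 1e-12)), n)
            if i1 <= i0:
                continue
            sims.append(departures[..., i0:i1].mean(axis=-1))
            obss.append(observed[i0:i1].mean())
        if not sims:
            raise ValueError("no segment overlaps the series")
        sim_m = np.stack(sims, axis=-1)
        obs_m = np.asarray(obss)
        return _batch_relative_rmse(sim_m, obs_m)
    raise ValueError(f"unknown scoring {scoring!r}")


def sweep_c(
    trial: TrialRecord,
    fixed: FeedbackParams,
    c_grid: Optional[Sequence[float]] = None,
    n_iterations: int = 200,
    seed: Optional[int] = None,
    scoring: str = "smoothed",
    smooth_radius: int = 25,
    mode: str = "stochastic",
) -> FitResult:
    """Grid sweep of c for one trial (thin wrapper over FeedbackCalibrator).

    For each candidate c the trial's returning series drives ``n_iterations``
    stochastic simulations; each is scored by relative RMSE against the
    observed outgoing series (smoothed-rate scoring by default) and the
    scores averaged. The best c is the argmin (ties broken toward the
    smallest c). ``mode="expectation"`` scores the single deterministic
    trajectory per candidate instead.
    """
    from .estimators import FeedbackCalibrator

    cal = FeedbackCalibrator(
        q=fixed.q,
        d=fixed.d,
        alpha_floor=fixed.alpha_floor,
        slot_duration=fixed.slot_duration,
        c_grid=c_grid,
        n_iterations=n_iterations,
        random_state=seed,
        scoring=scoring,
        smooth_radius=smooth_radius,
        mode=mode,
    )
    cal.fit(trial.returning, trial.outgoing)
    return cal.fit_result_


def replicate_rmse(
    trial_returning: SlotSeries,
    params: FeedbackParams,
    n_repeats: int = 200,
    seed: Optional[int] = None,
    mode: str = "stochastic",
) -> ReplicateRMSE:
    """Relative RMSE among replicate simulated outgoing traces.

    Quantifies how much disagreement the model's own departure randomness
    produces at fixed parameters: large at low return rates (departures
    hover near the floor and are noise-dominated), small at high rates.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if mode == "expectation":
        # replicates are identical by construction
        zeros = np.zeros(n_repeats)
        return ReplicateRMSE(zeros, zeros.copy())
    rng = np.random.default_rng(seed)
    reps = simulate_feedback_batch(
        trial_returning, params, np.array([params.c]), 3 * n_repeats, rng
    )[0].reshape(n_repeats, 3, -1)
    a, b, c = reps[:, 0], reps[:, 1], reps[:, 2]
    mean_a = a.mean(axis=-1)
    if np.any(mean_a <= 0):
        raise ValueError("reference replicate has zero mean; rate too low to score")
    ab = np.sqrt(np.mean((b - a) ** 2, axis=-1)) / mean_a
    ac = np.sqrt(np.mean((c - a) ** 2, axis=-1)) / mean_a
    return ReplicateRMSE(ab, ac)


def heldout_colony_c(
    trials_by_colony: Mapping[str, Sequence[TrialRecord]],
    fixed: FeedbackParams,
    c_grid: Optional[Sequence[float]] = None,
    n_iterations: int = 200,
    seed: Optional[int] = None,
    fit_indices: Optional[Mapping[str, tuple[int, int]]] = None,
    scoring: str = "smoothed",
    smooth_radius: int = 25,
    mode: str = "stochastic",
) -> HeldoutColonyResult:
    """Held-out evaluation of a colony-averaged c.

    Per colony: fit c independently on two designated trials, average the
    two best values, then simulate each remaining trial with the averaged c
    and report its mean relative RMSE over ``n_iterations`` runs. Colonies
    with fewer than 3 trials are skipped with a warning. The two fitting
    trials are chosen by ``fit_indices`` when supplied, otherwise by a
    seeded random draw.
    """
    ss = np.random.SeedSequence(seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    per_c: dict[str, float] = {}
    per_rmse: dict[str, list[float]] = {}
    skipped: list[str] = []
    for colony, trials in trials_by_colony.items():
        trials = list(trials)
        if len(trials) < 3:
            logger.warning("colony %s has < 3 trials; skipped", colony)
            skipped.append(colony)
            continue
        if fit_indices is not None and colony in fit_indices:
            i, j = fit_indices[colony]
        else:
            i, j = pick_rng.choice(len(trials), size=2, replace=False)
        fit_seeds = ss.spawn(2)
        best = [
            sweep_c(
                trials[k], fixed, c_grid, n_iterations,
                int(s.generate_state(1)[0] % (2**31)),
                scoring=scoring, smooth_radius=smooth_radius, mode=mode,
            ).best_c
            for k, s in zip((i, j), fit_seeds)
        ]
        avg_c = float(np.mean(best))
        per_c[colony] = avg_c
        score_rng = np.random.default_rng(ss.spawn(1)[0])
        rmses = []
        for k, trial in enumerate(trials):
            if k in (i, j):
                continue
            if mode == "expectation":
                from .model import simulate_feedback

                deps = simulate_feedback(
                    trial.returning, fixed.with_c(avg_c), mode="expectation"
                ).departures.counts[np.newaxis, :]
            else:
                deps = simulate_feedback_batch(
                    trial.returning, fixed, np.array([avg_c]),
                    n_iterations, score_rng,
                )[0]
            rmses.append(
                float(
                    score_batch(
                        deps, trial.outgoing.counts, scoring, smooth_radius,
                        fixed.slot_duration,
                    ).mean()
                )
            )
        per_rmse[colony] = rmses
    return HeldoutColonyResult(per_c, per_rmse, tuple(skipped))
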