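"""CSV interchange formats and YAML configuration.

Event traces travel as CSV with columns ``time`` (seconds), ``direction``
(``returning``/``outgoing``) and ``trial_id``; synthetic and field-derived
data are interchangeable. Fit results and correlation records are written
as plain CSV tables. Configuration files are YAML key-value mappings
mirroring FeedbackParams, TrialDesign and the sweep settings.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import FitResult
from .structures import DIRECTIONS, EventTrace, FeedbackParams, TrialDesign
from .traces import CorrelationRecord

__all__ = [
    "read_trace",
    "write_trace",
    "write_fit_result",
    "write_correlation_records",
    "load_config",
    "params_from_config",
    "design_from_config",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("time", "direction", "trial_id")


def read_trace(path: Union[str, Path]) -> dict[tuple[str, str], EventTrace]:
    """Read an event-trace CSV, grouped by (trial_id, direction).

    Malformed rows (bad direction token, non-numeric or negative time) are
    rejected with their line numbers. Out-of-order times are sorted with a
    logged notice.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"trial_id": str})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    lines = df.index + 2  # header is line 1
    times = pd.to_numeric(df["time"], errors="coerce")
    bad = times.isna() | (times < 0)
    if bad.any():
        raise ValueError(
            f"{path}: non-numeric or negative time on line(s) "
            f"{list(lines[bad])[:10]}"
        )
    bad_dir = ~df["direction"].isin(DIRECTIONS)
    if bad_dir.any():
        first = int(np.flatnonzero(bad_dir)[0])
        raise ValueError(
            f"{path}: bad direction {df['direction'].iloc[first]!r} on line "
            f"{int(lines[bad_dir][0])} (expected one of {DIRECTIONS})"
        )
    df = df.assign(time=times.astype(float))
    traces: dict[tuple[str, str], EventTrace] = {}
    for (trial_id, direction), group in df.groupby(["trial_id", "direction"], sort=True):
        t = group["time"].to_numpy()
        if np.any(np.diff(t) < 0):
            logger.info("%s: times for (%s, %s) were unsorted; sorting",
                        path, trial_id, direction)
            t = np.sort(t)
        traces[(str(trial_id), str(direction))] = EventTrace(t, str(direction))
    return traces


def write_trace(
    path: Union[str, Path],
    traces: Mapping[tuple[str, str], EventTrace],
) -> None:
    """Write traces to the event CSV format read by :func:`read_trace`."""
    rows = []
    for (trial_id, direction), trace in traces.items():
        for t in trace.times:
            rows.append((t, direction, trial_id))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def write_fit_result(path: Union[str, Path], result: FitResult) -> None:
    """RMSE-vs-c curve as CSV plus a summary row for the chosen c."""
    df = pd.DataFrame({"c": result.c_grid, "mean_rmse": result.mean_rmse_per_c})
    df["is_best"] = df["c"] == result.best_c
    df.to_csv(path, index=False)


def write_correlation_records(
    path: Union[str, Path], records: Iterable[CorrelationRecord]
) -> None:
    """One row per trial: mean return rate plus both correlations."""
    pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "mean_return_rate": r.mean_return_rate,
                "r_observed": r.r_observed,
                "r_simulated": r.r_simulated,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return cfg


def params_from_config(cfg: Mapping, c: float | None = None) -> FeedbackParams:
    """Build FeedbackParams from a config mapping; explicit c overrides."""
    return FeedbackParams(
        c=float(c if c is not None else cfg.get("c", 0.1)),
        q=float(cfg.get("q", 0.05)),
        d=float(cfg.get("d", 0.0)),
        alpha_floor=float(cfg.get("alpha_floor", 0.01)),
        slot_duration=float(cfg.get("slot_duration", 1.0)),
    )


def design_from_config(cfg: Mapping) -> TrialDesign:
    def _pair(key, default):
        v = cfg.get(key, default)
        return (float(v[0]), float(v[1]))

    return TrialDesign(
        pre_window=_pair("pre_window", (0.0, 240.0)),
        removal_window=_pair("removal_window", (240.0, 430.0)),
        post_window=_pair("post_window", (500.0, 1100.0)),
        travel_time=float(cfg.get("travel_time", 0.0)),
    )
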