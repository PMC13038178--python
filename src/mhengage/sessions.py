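"""Event-log ingestion, windowing and gap-based sessionization.

An app-usage *session* is a maximal run of consecutive events whose
inter-event gaps are all strictly below a gap threshold tau (in minutes):
a gap >= tau starts a new session. The operating threshold is chosen by
sweeping tau over a grid, counting total sessions N(tau), and locating the
elbow of the (nonincreasing) curve — operationalized as the interior grid
point maximizing the discrete second difference of N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReadResult",
    "SessionCountCurve",
    "ElbowResult",
    "read_events",
    "window_events",
    "sessionize",
    "sessionize_all",
    "threshold_sweep",
    "select_elbow",
    "DEFAULT_GRID",
]

#: Threshold grid swept by default: 0-60 minutes in 10-minute increments.
DEFAULT_GRID: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

EVENT_COLUMNS = ["participant_id", "timestamp"]


@dataclass
class ReadResult:
    """Parsed events plus a row-level rejection report."""

    events: pd.DataFrame
    n_rows: int
    n_rejected: int
    errors: list[str] = field(default_factory=list)


def _finalize_events(frame: pd.DataFrame, max_bad_fraction: float) -> ReadResult:
    n_rows = len(frame)
    ts = pd.to_datetime(frame["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna() | frame["participant_id"].isna()
    errors = [
        f"row {idx}: unparseable timestamp {frame['timestamp'].iloc[pos]!r}"
        for pos, idx in enumerate(frame.index)
        if bad.iloc[pos]
    ]
    n_rejected = int(bad.sum())
    if n_rows and n_rejected / n_rows > max_bad_fraction:
        raise ValueError(
            f"{n_rejected}/{n_rows} rows malformed, above tolerance {max_bad_fraction:.0%}"
        )
    events = pd.DataFrame(
        {
            "participant_id": frame.loc[~bad, "participant_id"].astype(str),
            "timestamp": ts[~bad].dt.floor("s"),
        }
    )
    events = events.sort_values(EVENT_COLUMNS, kind="mergesort").reset_index(drop=True)
    return ReadResult(events, n_rows, n_rejected, errors)


def read_events(source: str | Path | IO[str], fmt: str | None = None,
                max_bad_fraction: float = 0.01) -> ReadResult:
    """Read an event log from CSV or JSONL.

    Expected fields: ``participant_id`` and an ISO-8601 ``timestamp``
    (interpreted as UTC; second resolution). Rows with unparseable
    timestamps are rejected individually and reported; the read aborts if
    more than ``max_bad_fraction`` of rows are malformed.
    """
    if fmt is None:
        fmt = "jsonl" if str(source).endswith((".jsonl", ".ndjson")) else "csv"
    if fmt == "csv":
        frame = pd.read_csv(source, dtype={"participant_id": str, "timestamp": str})
    elif fmt == "jsonl":
        frame = pd.read_json(source, lines=True, dtype={"participant_id": str, "timestamp": str})
        if frame.empty:
            frame = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        raise ValueError(f"unknown event-log format {fmt!r}")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event log missing required column(s): {missing}")
    return _finalize_events(frame[EVENT_COLUMNS].copy(), max_bad_fraction)


def window_events(events: pd.DataFrame, enrollment: Mapping[str, pd.Timestamp] | pd.Series,
                  days: int = 28) -> pd.DataFrame:
    """Restrict events to each participant's intervention window.

    The window is half-open: ``enrollment <= t < enrollment + days * 24 h``.
    Every participant appearing in ``events`` must have an enrollment
    instant.
    """
    enrollment = pd.Series(dict(enrollment))
    if not enrollment.empty:
        enrollment = pd.to_datetime(enrollment, utc=True)
    if events.empty:
        return events.copy()
    present = pd.Index(events["participant_id"].unique())
    unknown = sorted(present.difference(enrollment.index))
    if unknown:
        raise KeyError(f"participants with events but no enrollment date: {unknown}")
    start = events["participant_id"].map(enrollment)
    end = start + pd.Timedelta(days=days)
    keep = (events["timestamp"] >= start) & (events["timestamp"] < end)
    return events.loc[keep].reset_index(drop=True)


def _gaps_minutes(timestamps) -> np.ndarray:
    t = pd.DatetimeIndex(timestamps).asi8 / 1e9  # seconds
    if np.any(np.diff(t) < 0):
        raise ValueError("events must be sorted ascending in time")
    return np.diff(t) / 60.0


def sessionize(events: pd.DataFrame, gap_threshold_min: float) -> pd.DataFrame:
    """Segment one participant's time-sorted events into sessions.

    Two consecutive events share a session iff their gap is strictly less
    than the threshold; a gap >= threshold starts a new session. With
    ``gap_threshold_min == 0`` every event is its own session.

    Returns a frame with columns participant_id, start, end, n_events,
    duration_min (raw end - start; any duration floor is applied by the
    engagement layer).
    """
    if gap_threshold_min < 0:
        raise ValueError("gap threshold must be >= 0")
    if events.empty:
        return pd.DataFrame(columns=["participant_id", "start", "end", "n_events", "duration_min"])
    pids = events["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("sessionize expects events of a single participant; use sessionize_all")
    ts = pd.DatetimeIndex(events["timestamp"])
    gaps = _gaps_minutes(ts)
    breaks = np.flatnonzero(gaps >= gap_threshold_min)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(ts) - 1]))
    out = pd.DataFrame(
        {
            "participant_id": pids[0],
            "start": ts[starts],
            "end": ts[ends],
            "n_events": ends - starts + 1,
        }
    )
    out["duration_min"] = (out["end"] - out["start"]).dt.total_seconds() / 60.0
    return out


def sessionize_all(events: pd.DataFrame, gap_threshold_min: float) -> pd.DataFrame:
    """Sessionize a multi-participant event log."""
    parts = [
        sessionize(grp, gap_threshold_min)
        for _, grp in events.groupby("participant_id", sort=True)
    ]
    if not parts:
        return sessionize(events, gap_threshold_min)
    return pd.concat(parts, ignore_index=True)


@dataclass
class SessionCountCurve:
    """Total session count N(tau) over the swept threshold grid, with the
    first difference N(tau) - N(tau - step)."""

    thresholds: np.ndarray
    counts: np.ndarray

    @property
    def first_diff(self) -> np.ndarray:
        return np.diff(self.counts)

    def to_frame(self) -> pd.DataFrame:
        fd = np.concatenate(([np.nan], self.first_diff))
        return pd.DataFrame(
            {"tau_min": self.thresholds, "n_sessions": self.counts, "first_diff": fd}
        )


def threshold_sweep(events: pd.DataFrame,
                    grid: Iterable[float] = DEFAULT_GRID) -> SessionCountCurve:
    """Count total sessions across all participants at each grid threshold.

    N(tau) is nonincreasing in tau: raising the threshold can only merge
    sessions. Computed from each participant's sorted inter-event gaps via
    ``n_sessions(tau) = 1 + #{gaps >= tau}``.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("threshold grid must be strictly increasing")
    counts = np.zeros(grid.size, dtype=np.int64)
    for _, grp in events.groupby("participant_id", sort=True):
        gaps = np.sort(_gaps_minutes(grp["timestamp"]))
        # gaps >= tau <=> index past searchsorted(gaps, tau, side="left")
        counts += 1 + (gaps.size - np.searchsorted(gaps, grid, side="left"))
    return SessionCountCurve(grid, counts)


@dataclass(frozen=True)
class ElbowResult:
    threshold_min: float
    method: str
    used_fallback: bool
    second_diffs: tuple[float, ...] = ()


def select_elbow(curve: SessionCountCurve, method: str = "second_difference",
                 fallback_min: float = 10.0) -> ElbowResult:
    """Choose the operating gap threshold from a session-count curve.

    ``second_difference`` returns the interior grid point maximizing the
    discrete second difference ``N(tau-step) - 2 N(tau) + N(tau+step)``
    (the knee, where the curve stops dropping steeply), ties broken toward
    the smallest tau. When no knee exists (maximum second difference <= 0,
    e.g. a linear or constant curve) the fallback threshold is returned and
    flagged. ``fixed`` always returns the fallback.
    """
    if method == "fixed":
        return ElbowResult(fallback_min, method, used_fallback=True)
    if method != "second_difference":
        raise ValueError(f"unknown elbow method {method!r}")
    n = np.asarray(curve.counts, dtype=float)
    if n.size < 3:
        raise ValueError("elbow selection needs at least 3 grid points")
    second = n[:-2] - 2.0 * n[1:-1] + n[2:]
    best = int(np.argmax(second))  # argmax takes the first (smallest tau) on ties
    if second[best] <= 0:
        return ElbowResult(fallback_min, method, used_fallback=True, second_diffs=tuple(second))
    return ElbowResult(float(curve.thresholds[best + 1]), method, False, tuple(second))


def write_sessions_csv(sessions: pd.DataFrame, path: str | Path) -> None:
    sessions.to_csv(path, index=False)


def write_curve_csv(curve: SessionCountCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)
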