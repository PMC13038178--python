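"""Per-participant engagement metrics and cohort stratification.

From a participant's sessions within a fixed intervention window this
module derives the usage summaries used for exploratory stratification:
cumulative usage time, average sessions per day, longest streak of
consecutive active calendar days (with >=14/21/28-day flags), inter-session
gap statistics, adherence (fraction of window days with at least one
session) and a regular/irregular usage-pattern label.

Calendar days are evaluated in a configurable timezone (default UTC); a
session is attributed to the day containing its start. Because a
single-event session has zero raw span, every session's duration is floored
at a small configurable value so cumulative minutes are not dominated by
zero-length sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EngagementProfile",
    "RegularityRule",
    "profile",
    "profile_all",
    "classify_regularity",
    "stratify",
    "STREAK_TIERS",
]

STREAK_TIERS = (14, 21, 28)

#: Default floor (minutes) applied to each session's duration.
DEFAULT_DURATION_FLOOR_MIN = 0.5


@dataclass(frozen=True)
class RegularityRule:
    """Operationalization of "regular" use: daily use with within-day
    inter-session intervals of at most ``max_gap_hours``.

    A participant is *regular* iff (a) the fraction of window days with at
    least one session is >= ``min_daily_coverage``, (b) every active day
    has at least ``min_sessions_per_day`` sessions (so within-day intervals
    exist at all; this encodes the morning/afternoon/evening reading of
    "intervals of 7 hours or less"), and (c) every within-day gap between
    consecutive sessions is <= ``max_gap_hours``. Overnight gaps are exempt
    — under daily coverage the next calendar day is always active.
    """

    max_gap_hours: float = 7.0
    min_daily_coverage: float = 1.0
    min_sessions_per_day: int = 2


@dataclass
class EngagementProfile:
    participant_id: str
    n_sessions: int
    total_usage_min: float
    sessions_per_day: float
    max_streak_days: int
    streak_ge_14: bool
    streak_ge_21: bool
    streak_ge_28: bool
    mean_gap_min: float  # NaN when fewer than 2 sessions
    sd_gap_min: float  # NaN when fewer than 3 sessions
    adherence: float
    regularity: str  # "regular" | "irregular"


def _session_days(sessions: pd.DataFrame, tz: str) -> pd.Series:
    return sessions["start"].dt.tz_convert(tz).dt.normalize()


def _max_streak(active_days: pd.Series) -> int:
    if active_days.empty:
        return 0
    ordinal = np.sort(pd.DatetimeIndex(active_days.unique()).asi8 // (86_400 * 10**9))
    # longest run of consecutive integers
    best = run = 1
    for prev, cur in zip(ordinal[:-1], ordinal[1:]):
        run = run + 1 if cur == prev + 1 else 1
        best = max(best, run)
    return best


def classify_regularity(sessions: pd.DataFrame, window_days: int,
                        rule: RegularityRule | None = None,
                        tz: str = "UTC") -> str:
    """Label one participant's usage pattern as "regular" or "irregular"."""
    rule = rule or RegularityRule()
    if sessions.empty:
        return "irregular"
    days = _session_days(sessions, tz)
    coverage = days.nunique() / window_days
    if coverage < rule.min_daily_coverage:
        return "irregular"
    for _, day_sessions in sessions.groupby(days, sort=True):
        if len(day_sessions) < rule.min_sessions_per_day:
            return "irregular"
        day_sessions = day_sessions.sort_values("start")
        gaps_h = (
            day_sessions["start"].iloc[1:].to_numpy()
            - day_sessions["end"].iloc[:-1].to_numpy()
        ) / np.timedelta64(1, "h")
        if np.any(gaps_h > rule.max_gap_hours):
            return "irregular"
    return "regular"


def profile(sessions: pd.DataFrame, enrollment: pd.Timestamp, window_days: int = 28,
            duration_floor_min: float = DEFAULT_DURATION_FLOOR_MIN,
            tz: str = "UTC", rule: RegularityRule | None = None,
            participant_id: str | None = None) -> EngagementProfile:
    """Summarize one participant's sessions into an engagement profile.

    ``sessions`` must be the participant's disjoint, time-ordered sessions,
    all within ``[enrollment, enrollment + window_days)``. A participant
    with no sessions gets zeros, undefined gap statistics (NaN) and the
    "irregular" label.
    """
    enrollment = pd.Timestamp(enrollment)
    if enrollment.tzinfo is None:
        enrollment = enrollment.tz_localize("UTC")
    if sessions.empty:
        if participant_id is None:
            raise ValueError("participant_id required when sessions are empty")
        return EngagementProfile(participant_id, 0, 0.0, 0.0, 0, False, False, False,
                                 float("nan"), float("nan"), 0.0, "irregular")
    sessions = sessions.sort_values("start").reset_index(drop=True)
    pid = participant_id or str(sessions["participant_id"].iloc[0])
    window_end = enrollment + pd.Timedelta(days=window_days)
    if (sessions["start"] < enrollment).any() or (sessions["end"] >= window_end).any():
        raise ValueError(f"sessions of {pid} fall outside the intervention window")

    durations = np.maximum(
        (sessions["end"] - sessions["start"]).dt.total_seconds() / 60.0,
        duration_floor_min,
    )
    n = len(sessions)
    days = _session_days(sessions, tz)
    streak = _max_streak(days)
    gaps_min = (
        sessions["start"].iloc[1:].to_numpy() - sessions["end"].iloc[:-1].to_numpy()
    ) / np.timedelta64(1, "m")
    mean_gap = float(np.mean(gaps_min)) if n >= 2 else float("nan")
    sd_gap = float(np.std(gaps_min, ddof=1)) if n >= 3 else float("nan")

    return EngagementProfile(
        participant_id=pid,
        n_sessions=n,
        total_usage_min=float(durations.sum()),
        sessions_per_day=n / window_days,
        max_streak_days=streak,
        streak_ge_14=streak >= 14,
        streak_ge_21=streak >= 21,
        streak_ge_28=streak >= 28,
        mean_gap_min=mean_gap,
        sd_gap_min=sd_gap,
        adherence=days.nunique() / window_days,
        regularity=classify_regularity(sessions, window_days, rule, tz),
    )


def profile_all(sessions: pd.DataFrame, enrollment: Mapping[str, pd.Timestamp] | pd.Series,
                window_days: int = 28,
                duration_floor_min: float = DEFAULT_DURATION_FLOOR_MIN,
                tz: str = "UTC", rule: RegularityRule | None = None) -> pd.DataFrame:
    """Profiles for every participant in the enrollment table (participants
    without sessions included, with zeroed metrics)."""
    enrollment = pd.to_datetime(pd.Series(dict(enrollment)), utc=True)
    grouped = dict(tuple(sessions.groupby("participant_id", sort=True))) if not sessions.empty else {}
    rows = []
    for pid in sorted(enrollment.index):
        sess = grouped.get(pid, sessions.iloc[0:0])
        prof = profile(sess, enrollment[pid], window_days, duration_floor_min, tz, rule,
                       participant_id=pid)
        rows.append(vars(prof))
    return pd.DataFrame(rows)


def stratify(profiles: pd.DataFrame, scheme: str, frequency_cutoff: float = 2.5,
             streak_days: int = 14) -> pd.Series:
    """Assign each participant to a stratum under one of the study's
    stratification schemes.

    - ``time_median``: high/low by total usage minutes at the cohort median
      (>= median is "high"; even n makes the median the midpoint of the
      central pair).
    - ``frequency``: high/low by sessions per day at an inclusive cutoff
      (default 2.5/day).
    - ``streak``: whether the longest consecutive-day streak reaches
      ``streak_days`` (14, 21 or 28).
    - ``regularity``: the stored regular/irregular label.
    """
    if profiles.empty:
        raise ValueError("profiles table is empty")
    idx = profiles["participant_id"]
    if scheme == "time_median":
        med = float(np.median(profiles["total_usage_min"]))
        labels = np.where(profiles["total_usage_min"] >= med, "high_time", "low_time")
    elif scheme == "frequency":
        labels = np.where(
            profiles["sessions_per_day"] >= frequency_cutoff, "high_frequency", "low_frequency"
        )
    elif scheme == "streak":
        labels = np.where(
            profiles["max_streak_days"] >= streak_days,
            f"streak_ge_{streak_days}", f"streak_lt_{streak_days}",
        )
    elif scheme == "regularity":
        labels = profiles["regularity"].to_numpy()
    else:
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    return pd.Series(labels, index=pd.Index(idx, name="participant_id"), name="stratum")
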