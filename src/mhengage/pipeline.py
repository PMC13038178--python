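"""End-to-end run orchestration: generate (or ingest) → window → sessionize
→ profile → score → analyze, with a manifest and a human-readable report.

A run is configured by a single :class:`RunConfig` (YAML/JSON-loadable) and
is deterministic: the same config and seed produce byte-identical output
files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .analysis import engagement_outcome_correlation, paired_change_table, score_changes
from .engagement import RegularityRule, profile_all, stratify
from .scoring import score_forms
from .sessions import (
    DEFAULT_GRID,
    read_events,
    select_elbow,
    sessionize_all,
    threshold_sweep,
    window_events,
)
from .simulate import SimConfig, generate_cohort

__all__ = ["RunConfig", "run", "report", "proportion_pct"]


class InputPaths(BaseModel):
    events: str
    enrollment: str
    forms: str
    participants: str | None = None


class SessionSettings(BaseModel):
    grid: list[float] = list(DEFAULT_GRID)
    elbow_method: str = "second_difference"
    fallback_min: float = 10.0


class EngagementSettings(BaseModel):
    window_days: int = Field(28, gt=0)
    duration_floor_min: float = Field(0.5, ge=0)
    timezone: str = "UTC"
    frequency_cutoff: float = Field(2.5, gt=0)
    streak_tiers: list[int] = [14, 21, 28]
    max_gap_hours: float = Field(7.0, gt=0)
    min_daily_coverage: float = Field(1.0, ge=0, le=1)
    min_sessions_per_day: int = Field(2, ge=1)


class AnalysisSettings(BaseModel):
    correlation_method: str = "spearman"
    correlation_metric: str = "total_usage_min"
    zero_method: str = "discard"
    alpha: float = Field(0.05, gt=0, lt=1)


class RunConfig(BaseModel):
    """Full pipeline configuration; exactly one of ``inputs``/``simulate``."""

    inputs: InputPaths | None = None
    simulate: SimConfig | None = None
    sessions: SessionSettings = SessionSettings()
    engagement: EngagementSettings = EngagementSettings()
    analysis: AnalysisSettings = AnalysisSettings()
    outdir: str = "mhengage_run"
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' and 'simulate' must be given")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


def proportion_pct(k: int, n: int, decimals: int = 1) -> float:
    """A count as a percentage of a total, rounded for reporting
    (e.g. 24 of 27 → 88.9)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, decimals)


def _write_csv(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, index=False)
    return len(frame)


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the pipeline and write all stage outputs plus the manifest.

    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    counts: dict[str, int] = {}

    # --- acquire inputs -------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate.model_copy(update={"seed": config.seed})
        cohort = generate_cohort(sim)
        events = cohort.events
        enrollment = cohort.enrollment
        participants = cohort.participants
        forms = cohort.forms
        counts["events_raw"] = len(events)
        cohort_truth = cohort.truth
        _write_csv(cohort_truth, outdir / "truth.csv")
    else:
        res = read_events(config.inputs.events)
        if res.n_rejected:
            warnings.append(f"{res.n_rejected} malformed event rows rejected")
        events = res.events
        counts["events_raw"] = res.n_rows
        enr = pd.read_csv(config.inputs.enrollment)
        enrollment = pd.Series(
            pd.to_datetime(enr["enrollment"], utc=True).to_numpy(),
            index=enr["participant_id"].astype(str),
        )
        forms = pd.read_csv(config.inputs.forms)
        participants = (pd.read_csv(config.inputs.participants)
                        if config.inputs.participants else None)

    # --- window + sessionize -------------------------------------------
    events = window_events(events, enrollment, days=config.engagement.window_days)
    counts["events_windowed"] = len(events)
    curve = threshold_sweep(events, config.sessions.grid)
    elbow = select_elbow(curve, config.sessions.elbow_method, config.sessions.fallback_min)
    if elbow.used_fallback and config.sessions.elbow_method != "fixed":
        warnings.append(f"no knee in session-count curve; fallback threshold "
                        f"{elbow.threshold_min} min used")
    sessions = sessionize_all(events, elbow.threshold_min)
    # reported durations carry the same floor the engagement metrics use
    sessions_out = sessions.copy()
    sessions_out["duration_min"] = np.maximum(
        sessions_out["duration_min"], config.engagement.duration_floor_min)
    counts["sessions"] = _write_csv(sessions_out, outdir / "sessions.csv")
    curve.to_frame().to_csv(outdir / "session_count_curve.csv", index=False)

    # --- engagement profiles + strata ----------------------------------
    rule = RegularityRule(config.engagement.max_gap_hours,
                          config.engagement.min_daily_coverage,
                          config.engagement.min_sessions_per_day)
    profiles = profile_all(sessions, enrollment, config.engagement.window_days,
                           config.engagement.duration_floor_min,
                           config.engagement.timezone, rule)
    counts["profiles"] = _write_csv(profiles, outdir / "profiles.csv")

    strata = {"time_median": stratify(profiles, "time_median"),
              "frequency": stratify(profiles, "frequency",
                                    frequency_cutoff=config.engagement.frequency_cutoff),
              "regularity": stratify(profiles, "regularity")}
    for k in config.engagement.streak_tiers:
        strata[f"streak_{k}"] = stratify(profiles, "streak", streak_days=k)
    strata_frame = pd.DataFrame(strata).reset_index()
    counts["strata"] = _write_csv(strata_frame, outdir / "strata.csv")

    # --- scoring --------------------------------------------------------
    scores = score_forms(forms)
    counts["scores"] = _write_csv(scores, outdir / "scores.csv")

    # --- analysis -------------------------------------------------------
    tables = [paired_change_table(scores, zero_method=config.analysis.zero_method)]
    for name, labels in strata.items():
        t = paired_change_table(scores, groups=labels,
                                zero_method=config.analysis.zero_method, exploratory=True)
        t.insert(0, "scheme", name)
        tables.append(t)
    paired = pd.concat(tables, ignore_index=True)
    paired["scheme"] = paired.get("scheme", pd.Series(dtype=object)).fillna("overall")
    paired = paired[["scheme"] + [c for c in paired.columns if c != "scheme"]]
    counts["paired_tests"] = _write_csv(paired, outdir / "paired_tests.csv")

    changes = score_changes(scores)
    corr_rows = []
    metric_vals = profiles.set_index("participant_id")[config.analysis.correlation_metric]
    for outcome in changes.columns:
        col = changes[outcome].dropna()
        if len(col) < 3 or col.nunique() <= 1 or metric_vals.loc[col.index].nunique() <= 1:
            continue
        c = engagement_outcome_correlation(profiles, changes,
                                           metric=config.analysis.correlation_metric,
                                           outcome=outcome,
                                           method=config.analysis.correlation_method)
        corr_rows.append({"metric": c.metric, "outcome": c.outcome, "r": c.r,
                          "p_value": c.p_value, "n": c.n, "method": c.method,
                          "exploratory": True})
    correlations = pd.DataFrame(corr_rows)
    counts["correlations"] = _write_csv(correlations, outdir / "correlations.csv")

    # outdir is implicit (the manifest lives there); leaving it out keeps
    # runs into different directories byte-comparable
    config_echo = json.loads(config.model_dump_json(exclude={"outdir"}))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_echo,
        "elbow_threshold_min": elbow.threshold_min,
        "elbow_used_fallback": elbow.used_fallback,
        "row_counts": counts,
        "warnings": warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if participants is not None:
        _write_csv(participants.assign(
            enrollment=participants["enrollment"].astype(str)),
            outdir / "participants.csv")
    (outdir / "report.txt").write_text(report(outdir))
    return manifest


def report(outdir: str | Path) -> str:
    """Human-readable feasibility summary of a completed run: retention,
    sessions/day, cumulative minutes, adherence and strata sizes."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {outdir}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    profiles = pd.read_csv(outdir / "profiles.csv")
    scores = pd.read_csv(outdir / "scores.csv")
    strata = pd.read_csv(outdir / "strata.csv")
    if profiles.empty:
        return "Empty cohort: no participants profiled; nothing to report.\n"

    enrolled = len(profiles)
    completers = scores.loc[scores["timepoint"] == "post", "participant_id"].nunique()
    lines = [
        "mhengage run summary",
        "====================",
        f"participants enrolled:      {enrolled}",
        f"completed post-assessment:  {completers}",
        f"retention:                  {completers}/{enrolled} = "
        f"{proportion_pct(completers, enrolled)}%",
        f"chosen session gap:         {manifest['elbow_threshold_min']:g} min"
        + (" (fallback)" if manifest["elbow_used_fallback"] else ""),
        f"mean sessions/day:          {profiles['sessions_per_day'].mean():.2f}",
        f"median cumulative use:      {profiles['total_usage_min'].median():.1f} min",
        f"median adherence:           {100 * profiles['adherence'].median():.1f}%",
        "",
        "strata sizes:",
    ]
    for scheme in [c for c in strata.columns if c != "participant_id"]:
        counts = strata[scheme].value_counts().sort_index()
        lines.append(f"  {scheme}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    return "\n".join(lines) + "\n"
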