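"""Seedable synthetic cohorts for a 4-week mobile-nutrition feasibility design.

Nothing individual-level is published for studies of this kind, so every
downstream stage (sessionization, engagement profiling, scoring, paired
analysis) is exercised against cohorts drawn from an explicit generative
model:

* between-participant engagement heterogeneity: lognormal daily session
  propensity (mean ~2.3 sessions/day, matching typical meal-logging use);
* within-day timing: session starts drawn from a Gaussian mixture anchored
  at meal times (default 08:00, 12:30, 19:00);
* within-session burstiness: 1 + Poisson event counts with
  truncated-exponential inter-event gaps kept strictly below the declared
  session gap, so ground-truth session membership is recoverable by
  sessionizing at that gap;
* attrition: a constant daily dropout hazard (geometric time to dropout);
  participants dropping out in the first two weeks contribute no
  post-intervention questionnaires;
* outcomes: pre scores drawn per scale around configurable baselines, post
  scores equal to pre plus a linear effect of standardized engagement
  (``beta`` points per engagement SD) plus Gaussian noise, realized through
  integer item responses and therefore quantized and bounded to [0, 100].

A single integer seed determines the whole cohort byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .scoring import (
    NQ2021,
    QLQC30,
    InstrumentSpec,
    QuestionnaireForm,
    load_nq2021_spec,
    load_qlqc30_spec,
)

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_event_log",
    "generate_item_responses",
    "write_cohort",
]

#: Demographic mix emulating a cancer-survivorship clinic population.
CANCER_TYPES = ("breast", "colorectal", "gastric", "lung", "thyroid", "lymphoma", "renal")
CANCER_PROBS = (11 / 24, 3 / 24, 3 / 24, 3 / 24, 2 / 24, 1 / 24, 1 / 24)
FEMALE_PROB = 17 / 24

#: Default baseline score levels (0-100 points) per scale, with SDs,
#: typical of disease-free cancer survivors; scales not listed fall back to
#: direction defaults.
DEFAULT_BASELINE_MEANS = {
    "balance": 59.3, "moderation": 76.6, "practice": 78.5,
    "global_health": 53.2, "appetite_loss": 17.9, "physical_functioning": 86.2,
}
DEFAULT_BASELINE_SDS = {
    "balance": 17.0, "moderation": 15.4, "practice": 13.2,
    "global_health": 12.5, "appetite_loss": 22.0, "physical_functioning": 12.3,
}
_FALLBACK_BASELINES = {"functional": (80.0, 15.0), "symptom": (15.0, 15.0),
                       "global": (60.0, 15.0)}


class SimConfig(BaseModel):
    """Configuration of the synthetic cohort generator."""

    n_participants: int = Field(27, gt=0)
    window_days: int = Field(28, gt=0)
    daily_session_rate_mean: float = Field(2.3, ge=0)
    daily_session_rate_sd: float = Field(0.9, ge=0)
    meal_anchors: list[float] = [8.0, 12.5, 19.0]
    anchor_sd_hours: float = Field(0.75, ge=0)
    events_per_session_mean: float = Field(53.0, ge=1)
    intra_session_gap_mean_min: float = Field(0.057, gt=0)
    session_gap_min: float = Field(10.0, gt=0)  # declared generator gap
    dropout_hazard_per_day: float = Field(0.004, ge=0, le=1)
    outcome_coupling_beta: dict[str, float] = {"moderation": 4.4, "appetite_loss": -4.0}
    outcome_noise_sd: float = Field(8.0, ge=0)
    baseline_score_means: dict[str, float] = dict(DEFAULT_BASELINE_MEANS)
    baseline_score_sds: dict[str, float] = dict(DEFAULT_BASELINE_SDS)
    enrollment_start: str = "2024-10-01"
    enrollment_span_days: int = Field(60, ge=0)
    seed: int = 0

    @field_validator("meal_anchors")
    @classmethod
    def _anchors_in_day(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("meal_anchors must be nonempty")
        if any(not (0 <= a < 24) for a in v):
            raise ValueError("meal_anchors must lie in [0, 24)")
        return v

    @field_validator("baseline_score_means")
    @classmethod
    def _means_in_range(cls, v: dict[str, float]) -> dict[str, float]:
        bad = {k: x for k, x in v.items() if not (0 <= x <= 100)}
        if bad:
            raise ValueError(f"baseline_score_means outside [0, 100]: {bad}")
        return v


@dataclass
class SyntheticCohort:
    """A generated cohort: who, when, what they tapped, and what they reported."""

    participants: pd.DataFrame  # id, sex, age, cancer_type, enrollment, completed
    events: pd.DataFrame  # participant_id, timestamp
    forms: pd.DataFrame  # participant_id, timepoint, instrument, item_id, response
    truth: pd.DataFrame  # latent propensity, dropout day, session bookkeeping, engagement z
    config: SimConfig

    @property
    def enrollment(self) -> pd.Series:
        return self.participants.set_index("participant_id")["enrollment"]


def _truncated_exponential(rng: np.random.Generator, mean: float, upper: float,
                           size: int) -> np.ndarray:
    """Exponential(mean) truncated to (0, upper) by inverse-CDF sampling."""
    u = rng.random(size)
    cap = 1.0 - math.exp(-upper / mean)
    return -mean * np.log1p(-u * cap)


def generate_event_log(propensity: float, window_start: pd.Timestamp, active_days: int,
                       rng: np.random.Generator, *,
                       meal_anchors: Sequence[float] = (8.0, 12.5, 19.0),
                       anchor_sd_hours: float = 0.75,
                       events_per_session_mean: float = 53.0,
                       intra_session_gap_mean_min: float = 0.057,
                       session_gap_min: float = 10.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One participant's bursty, meal-anchored event stream.

    Per active day the number of sessions is Poisson(propensity); each
    session starts near a randomly chosen meal anchor and contains
    ``1 + Poisson(events_per_session_mean - 1)`` events whose gaps are
    truncated-exponential, strictly below the declared session gap (with a
    2-second margin so second-rounding cannot blur session boundaries).
    Consecutive sessions are forced at least the declared gap apart, so
    sessionizing the log at that gap recovers the ground-truth sessions.

    Returns (events, true_sessions); timestamps are UTC at second resolution.
    """
    if propensity < 0:
        raise ValueError("session propensity must be >= 0")
    window_start = pd.Timestamp(window_start)
    if window_start.tzinfo is None:
        window_start = window_start.tz_localize("UTC")
    starts_min: list[float] = []  # minutes since window start
    for day in range(active_days):
        for _ in range(rng.poisson(propensity)):
            anchor = meal_anchors[rng.integers(len(meal_anchors))]
            hour = float(np.clip(rng.normal(anchor, anchor_sd_hours), 0.0, 23.75))
            starts_min.append(day * 1440.0 + hour * 60.0)
    starts_min.sort()

    gap_margin_min = session_gap_min - 2.0 / 60.0  # intra-gap cap, rounding-safe
    events_all: list[np.ndarray] = []
    sess_rows = []
    prev_end = -math.inf
    budget_min = active_days * 1440.0 - 15.0  # keep sessions inside the window
    for s in starts_min:
        start = max(s, prev_end + session_gap_min + 2.0 / 60.0)
        if start > budget_min:
            continue
        n_events = 1 + int(rng.poisson(events_per_session_mean - 1.0))
        gaps = _truncated_exponential(rng, intra_session_gap_mean_min, gap_margin_min,
                                      n_events - 1)
        offsets = np.concatenate(([0.0], np.cumsum(gaps)))
        times = start + offsets
        events_all.append(times)
        sess_rows.append({"start_min": times[0], "end_min": times[-1], "n_events": n_events})
        prev_end = times[-1]

    if events_all:
        minutes = np.concatenate(events_all)
        stamps = window_start + pd.to_timedelta(np.round(minutes * 60.0), unit="s")
    else:
        stamps = pd.DatetimeIndex([], tz="UTC")
    events = pd.DataFrame({"timestamp": stamps})
    true_sessions = pd.DataFrame(sess_rows, columns=["start_min", "end_min", "n_events"])
    return events, true_sessions


def _targets_for_instrument(spec: InstrumentSpec, overrides: Mapping[str, float]) -> dict[str, float]:
    targets = {}
    for s in spec.scales:
        if s.name in overrides:
            targets[s.name] = overrides[s.name]
        else:
            targets[s.name] = _FALLBACK_BASELINES.get(s.direction, (60.0, 15.0))[0]
    return targets


def _distribute_units(k: int, total: int) -> np.ndarray:
    """Split ``total`` integer units over k items as evenly as possible."""
    q, r = divmod(total, k)
    units = np.full(k, q, dtype=int)
    units[:r] += 1
    return units


def generate_item_responses(target_scores: Mapping[str, float], instrument: str,
                            participant_id: str, timepoint: str) -> QuestionnaireForm:
    """Integer item responses whose scores reproduce the targets up to the
    scale's quantization step.

    For each scale the target is inverted through the scoring formula to a
    total integer "offset budget" spread as evenly as possible over the
    scale's items; re-scoring the form returns the target within half a
    quantization step (``100 / (n_items * range)`` points). Deterministic
    given the targets.
    """
    for name, t in target_scores.items():
        if not 0 <= t <= 100:
            raise ValueError(f"target score for {name!r} outside [0, 100]: {t}")
    responses: dict[str, int] = {}
    if instrument == QLQC30:
        spec = load_qlqc30_spec()
        for s in spec.scales:
            t = target_scores.get(s.name, 50.0)
            # functional: t = (1 - m/range)*100 ; symptom/global: t = (m/range)*100
            m = (1.0 - t / 100.0) * s.item_range if s.direction == "functional" \
                else (t / 100.0) * s.item_range
            total = round(m * len(s.items))
            for item, off in zip(s.items, _distribute_units(len(s.items), total)):
                responses[item] = spec.item_ranges[item][0] + int(off)
    elif instrument == NQ2021:
        spec = load_nq2021_spec()
        for s in spec.scales:
            t = target_scores.get(s.name, 50.0)
            spans = [spec.item_ranges[i][1] - spec.item_ranges[i][0] for i in s.items]
            total = round(t / 100.0 * sum(spans))
            for item, off in zip(s.items, _distribute_units(len(s.items), total)):
                lo, hi = spec.item_ranges[item]
                responses[item] = hi - int(off) if item in spec.reverse_items else lo + int(off)
    else:
        raise ValueError(f"unknown instrument {instrument!r}")
    return QuestionnaireForm(participant_id, timepoint, instrument, responses)


def _draw_pre_targets(spec: InstrumentSpec, cfg: SimConfig,
                      rng: np.random.Generator) -> dict[str, float]:
    targets = {}
    for s in spec.scales:
        if s.name in cfg.baseline_score_means:
            mean = cfg.baseline_score_means[s.name]
            sd = cfg.baseline_score_sds.get(s.name, 15.0)
        else:
            mean, sd = _FALLBACK_BASELINES.get(s.direction, (60.0, 15.0))
        targets[s.name] = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
    return targets


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under one seed.

    Event logs run from each participant's enrollment until dropout (or the
    end of the window); dropouts within the first 14 days contribute no
    post forms. Post questionnaire targets are
    ``pre + beta_scale * engagement_z + N(0, noise_sd)`` clipped to
    [0, 100], with engagement_z the cohort-standardized true total usage
    time.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_attrs, ss_events, ss_forms = root.spawn(3)
    rng_attrs = np.random.default_rng(ss_attrs)
    event_rngs = [np.random.default_rng(s) for s in ss_events.spawn(cfg.n_participants)]
    rng_forms = np.random.default_rng(ss_forms)

    n = cfg.n_participants
    ids = [f"P{i + 1:03d}" for i in range(n)]
    sex = np.where(rng_attrs.random(n) < FEMALE_PROB, "F", "M")
    age = np.clip(np.round(rng_attrs.normal(58.5, 8.7, n)), 20, 69).astype(int)
    cancer = rng_attrs.choice(CANCER_TYPES, size=n, p=CANCER_PROBS)
    enroll_base = pd.Timestamp(cfg.enrollment_start, tz="UTC")
    offsets = rng_attrs.integers(0, cfg.enrollment_span_days + 1, size=n)
    enrollment = enroll_base + pd.to_timedelta(offsets, unit="D")

    # lognormal propensity with the configured mean/SD across participants
    if cfg.daily_session_rate_mean > 0 and cfg.daily_session_rate_sd > 0:
        cv2 = (cfg.daily_session_rate_sd / cfg.daily_session_rate_mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(cfg.daily_session_rate_mean) - 0.5 * sigma ** 2
        propensity = rng_attrs.lognormal(mu, sigma, n)
    else:
        propensity = np.full(n, cfg.daily_session_rate_mean)

    # geometric dropout: app use stops after the first day with a hazard hit
    if cfg.dropout_hazard_per_day > 0:
        geom = rng_attrs.geometric(cfg.dropout_hazard_per_day, n)
    else:
        geom = np.full(n, cfg.window_days + 1)
    dropped = geom <= cfg.window_days
    active_days = np.minimum(geom, cfg.window_days)  # use through the dropout day
    completed = geom > 14  # post forms absent only for early dropouts

    events_frames = []
    truth_rows = []
    for i, pid in enumerate(ids):
        ev, true_sess = generate_event_log(
            propensity[i], enrollment[i], int(active_days[i]), event_rngs[i],
            meal_anchors=cfg.meal_anchors, anchor_sd_hours=cfg.anchor_sd_hours,
            events_per_session_mean=cfg.events_per_session_mean,
            intra_session_gap_mean_min=cfg.intra_session_gap_mean_min,
            session_gap_min=cfg.session_gap_min,
        )
        ev.insert(0, "participant_id", pid)
        events_frames.append(ev)
        total_min = float((true_sess["end_min"] - true_sess["start_min"]).sum())
        truth_rows.append(
            {"participant_id": pid, "propensity": propensity[i],
             "dropout_day": int(geom[i]) if dropped[i] else None,
             "completed": bool(completed[i]), "n_true_sessions": len(true_sess),
             "true_total_min": total_min}
        )
    events = pd.concat(events_frames, ignore_index=True)
    events = events.sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)

    usage = truth["true_total_min"].to_numpy(dtype=float)
    sd = usage.std(ddof=0)
    truth["engagement_z"] = (usage - usage.mean()) / sd if sd > 0 else 0.0

    qlq_spec = load_qlqc30_spec()
    nq_spec = load_nq2021_spec()
    form_rows = []
    for i, pid in enumerate(ids):
        z = float(truth["engagement_z"].iloc[i])
        for spec, inst in ((nq_spec, NQ2021), (qlq_spec, QLQC30)):
            pre_targets = _draw_pre_targets(spec, cfg, rng_forms)
            post_targets = {
                name: float(np.clip(
                    t + cfg.outcome_coupling_beta.get(name, 0.0) * z
                    + rng_forms.normal(0.0, cfg.outcome_noise_sd), 0.0, 100.0))
                for name, t in pre_targets.items()
            }
            timepoints = [("pre", pre_targets)]
            if completed[i]:
                timepoints.append(("post", post_targets))
            for tp, targets in timepoints:
                form = generate_item_responses(targets, inst, pid, tp)
                for item, resp in form.responses.items():
                    form_rows.append({"participant_id": pid, "timepoint": tp,
                                      "instrument": inst, "item_id": item, "response": resp})
    forms = pd.DataFrame(form_rows)

    participants = pd.DataFrame(
        {"participant_id": ids, "sex": sex, "age": age, "cancer_type": cancer,
         "enrollment": enrollment, "completed": completed}
    )
    return SyntheticCohort(participants, events, forms, truth, cfg)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 events_format: str = "csv") -> dict[str, str]:
    """Write a cohort to disk (CSV tables, optional JSONL events) plus a
    manifest recording the config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    events = cohort.events.copy()
    events["timestamp"] = events["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    if events_format == "csv":
        paths["events"] = str(outdir / "events.csv")
        events.to_csv(paths["events"], index=False)
    elif events_format == "jsonl":
        paths["events"] = str(outdir / "events.jsonl")
        events.to_json(paths["events"], orient="records", lines=True)
    else:
        raise ValueError(f"unknown events format {events_format!r}")

    participants = cohort.participants.copy()
    participants["enrollment"] = participants["enrollment"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    paths["participants"] = str(outdir / "participants.csv")
    participants.to_csv(paths["participants"], index=False)
    paths["enrollment"] = str(outdir / "enrollment.csv")
    participants[["participant_id", "enrollment"]].to_csv(paths["enrollment"], index=False)
    paths["forms"] = str(outdir / "forms.csv")
    cohort.forms.to_csv(paths["forms"], index=False)
    paths["truth"] = str(outdir / "truth.csv")
    cohort.truth.to_csv(paths["truth"], index=False)

    manifest = {"seed": cohort.config.seed, "config": cohort.config.model_dump(),
                "n_events": len(cohort.events), "n_participants": len(cohort.participants)}
    paths["manifest"] = str(outdir / "cohort_manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
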