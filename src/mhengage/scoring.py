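"""Patient-reported-outcome scoring: EORTC QLQ-C30 (v3.0) and NQ-2021.

Both instruments are scored to 0-100 scales. The QLQ-C30 follows the EORTC
scoring manual: for each scale the raw score RS is the mean of the answered
items; functional scales use ``(1 - (RS - 1) / range) * 100`` (higher =
better functioning) while symptom scales and global health use
``((RS - 1) / range) * 100``. The "half rule" applies throughout: a
multi-item scale is scored only when at least half of its items are
answered.

The NQ-2021 (Nutrition Quotient for Adults) is scored as a weighted mean of
items normalized to [0, 1] by their response range and keying direction,
then rescaled to 0-100 per domain (Balance, Moderation, Practice) with a
weighted total. The official item weights are not public; the bundled
default configuration is an equal-weight stand-in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "InstrumentSpec",
    "QuestionnaireForm",
    "DomainScore",
    "ValidationReport",
    "load_qlqc30_spec",
    "load_nq2021_spec",
    "load_default_nq_weights",
    "score_qlqc30",
    "score_nq2021",
    "score_form",
    "score_forms",
    "validate_form",
]

QLQC30 = "QLQ-C30"
NQ2021 = "NQ-2021"


@dataclass(frozen=True)
class ScaleDef:
    """One scale of an instrument: its items, direction and score range."""

    name: str
    items: tuple[str, ...]
    direction: str  # "functional" | "symptom" | "global"
    item_range: float  # RS range (max - min of the raw item score)


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    item_ranges: dict[str, tuple[int, int]]
    scales: tuple[ScaleDef, ...]
    reverse_items: frozenset[str] = frozenset()
    aliases: Mapping[str, str] = field(default_factory=dict)

    def scale(self, name: str) -> ScaleDef:
        canonical = self.aliases.get(name, name)
        for s in self.scales:
            if s.name == canonical:
                return s
        raise KeyError(f"unknown scale {name!r} for instrument {self.name}")

    @property
    def scale_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.scales)


@dataclass
class QuestionnaireForm:
    """Item-level responses for one participant, instrument and timepoint."""

    participant_id: str
    timepoint: str  # "pre" | "post"
    instrument: str
    responses: dict[str, int | None]


@dataclass(frozen=True)
class DomainScore:
    participant_id: str
    timepoint: str
    scale: str
    score: float | None  # None when the half rule is not met
    n_answered: int
    n_items: int


@dataclass
class ValidationReport:
    out_of_range: list[tuple[str, int]] = field(default_factory=list)
    unknown_items: list[str] = field(default_factory=list)
    half_rule_flags: list[str] = field(default_factory=list)  # scales at risk

    @property
    def ok(self) -> bool:
        return not (self.out_of_range or self.unknown_items or self.half_rule_flags)


def _load_json(name: str) -> dict:
    with resources.files("mhengage.instruments").joinpath(name).open() as fh:
        return json.load(fh)


def load_qlqc30_spec() -> InstrumentSpec:
    raw = _load_json("qlqc30.json")
    scales = tuple(
        ScaleDef(s["name"], tuple(s["items"]), s["direction"], float(s["range"]))
        for s in raw["scales"]
    )
    ranges = {k: (int(v[0]), int(v[1])) for k, v in raw["items"].items()}
    return InstrumentSpec(raw["name"], ranges, scales)


def load_nq2021_spec() -> InstrumentSpec:
    raw = _load_json("nq2021.json")
    ranges = {k: (int(v["range"][0]), int(v["range"][1])) for k, v in raw["items"].items()}
    reverse = frozenset(k for k, v in raw["items"].items() if v["reverse"])
    scales = tuple(
        ScaleDef(dom, tuple(items), "functional", 0.0)
        for dom, items in raw["domains"].items()
    )
    return InstrumentSpec(raw["name"], ranges, scales, reverse, dict(raw.get("aliases", {})))


def load_default_nq_weights() -> dict:
    return _load_json("nq2021_weights_default.json")


def _half_rule_met(n_answered: int, n_items: int) -> bool:
    return n_answered >= math.ceil(n_items / 2)


def validate_form(form: QuestionnaireForm, spec: InstrumentSpec) -> ValidationReport:
    """Report out-of-range responses, unknown items and scales at risk of
    failing the half rule. Report-only: never raises."""
    report = ValidationReport()
    for item, resp in form.responses.items():
        if item not in spec.item_ranges:
            report.unknown_items.append(item)
            continue
        if resp is None:
            continue
        lo, hi = spec.item_ranges[item]
        if not (lo <= resp <= hi):
            report.out_of_range.append((item, resp))
    for s in spec.scales:
        n_ans = sum(1 for i in s.items if form.responses.get(i) is not None)
        if not _half_rule_met(n_ans, len(s.items)):
            report.half_rule_flags.append(s.name)
    return report


def _check_ranges(form: QuestionnaireForm, spec: InstrumentSpec) -> None:
    for item, resp in form.responses.items():
        if resp is None or item not in spec.item_ranges:
            continue
        lo, hi = spec.item_ranges[item]
        if not (lo <= resp <= hi):
            raise ValueError(
                f"response {resp} for item {item!r} outside declared range [{lo}, {hi}]"
            )


def score_qlqc30(form: QuestionnaireForm) -> list[DomainScore]:
    """Score all 15 QLQ-C30 scales of one form.

    Raw score is the mean of answered items (half rule); the linear
    transform maps it to 0-100 with direction-dependent orientation.
    """
    if form.instrument != QLQC30:
        raise ValueError(f"form declares instrument {form.instrument!r}, expected {QLQC30!r}")
    spec = load_qlqc30_spec()
    _check_ranges(form, spec)
    out: list[DomainScore] = []
    for s in spec.scales:
        answered = [form.responses[i] for i in s.items if form.responses.get(i) is not None]
        n_ans = len(answered)
        if not _half_rule_met(n_ans, len(s.items)):
            out.append(DomainScore(form.participant_id, form.timepoint, s.name, None, n_ans, len(s.items)))
            continue
        rs = sum(answered) / n_ans
        if s.direction == "functional":
            score = (1.0 - (rs - 1.0) / s.item_range) * 100.0
        else:  # symptom scales and global health share the orientation
            score = ((rs - 1.0) / s.item_range) * 100.0
        out.append(DomainScore(form.participant_id, form.timepoint, s.name, score, n_ans, len(s.items)))
    return out


def score_nq2021(form: QuestionnaireForm, weights: dict | None = None) -> list[DomainScore]:
    """Score the three NQ-2021 domains plus the weighted total.

    Each item response is normalized to u in [0, 1] by its response range
    and keying direction (reverse-keyed Moderation items score high for low
    frequency of unhealthy behaviour); the domain score is
    ``100 * sum(w_i * u_i) / sum(w_i)`` over answered items, subject to the
    half rule; the total is the domain-weighted mean of available domains.
    """
    if form.instrument != NQ2021:
        raise ValueError(f"form declares instrument {form.instrument!r}, expected {NQ2021!r}")
    spec = load_nq2021_spec()
    _check_ranges(form, spec)
    if weights is None:
        weights = load_default_nq_weights()
    item_w = weights["item_weights"]
    domain_w = weights["domain_weights"]

    out: list[DomainScore] = []
    domain_scores: dict[str, float | None] = {}
    for s in spec.scales:
        missing_w = [i for i in s.items if i not in item_w]
        if missing_w:
            raise KeyError(f"weight configuration missing items {missing_w} for domain {s.name!r}")
        num = den = 0.0
        n_ans = 0
        for i in s.items:
            resp = form.responses.get(i)
            if resp is None:
                continue
            lo, hi = spec.item_ranges[i]
            u = (hi - resp) / (hi - lo) if i in spec.reverse_items else (resp - lo) / (hi - lo)
            num += item_w[i] * u
            den += item_w[i]
            n_ans += 1
        score = 100.0 * num / den if _half_rule_met(n_ans, len(s.items)) and den > 0 else None
        domain_scores[s.name] = score
        out.append(DomainScore(form.participant_id, form.timepoint, s.name, score, n_ans, len(s.items)))

    avail = {d: v for d, v in domain_scores.items() if v is not None}
    if _half_rule_met(len(avail), len(spec.scales)):
        wsum = sum(domain_w[d] for d in avail)
        total = sum(domain_w[d] * v for d, v in avail.items()) / wsum
    else:
        total = None
    out.append(
        DomainScore(form.participant_id, form.timepoint, "nutritional_score", total,
                    sum(1 for v in form.responses.values() if v is not None), len(spec.item_ranges))
    )
    return out


def score_form(form: QuestionnaireForm, nq_weights: dict | None = None) -> list[DomainScore]:
    if form.instrument == QLQC30:
        return score_qlqc30(form)
    if form.instrument == NQ2021:
        return score_nq2021(form, nq_weights)
    raise ValueError(f"unknown instrument {form.instrument!r}")


def forms_from_frame(frame: pd.DataFrame) -> list[QuestionnaireForm]:
    """Reassemble forms from a long table with columns
    participant_id, timepoint, instrument, item_id, response."""
    forms = []
    for (pid, tp, inst), grp in frame.groupby(
        ["participant_id", "timepoint", "instrument"], sort=True
    ):
        responses = {
            row.item_id: (None if pd.isna(row.response) else int(row.response))
            for row in grp.itertuples()
        }
        forms.append(QuestionnaireForm(str(pid), str(tp), str(inst), responses))
    return forms


def score_forms(forms: Iterable[QuestionnaireForm] | pd.DataFrame,
                nq_weights: dict | None = None) -> pd.DataFrame:
    """Score a collection of forms into a long scores table
    (participant_id, timepoint, instrument, scale, score, n_answered, n_items)."""
    if isinstance(forms, pd.DataFrame):
        forms = forms_from_frame(forms)
    rows = []
    for form in forms:
        for ds in score_form(form, nq_weights):
            rows.append(
                {
                    "participant_id": ds.participant_id,
                    "timepoint": ds.timepoint,
                    "instrument": form.instrument,
                    "scale": ds.scale,
                    "score": ds.score,
                    "n_answered": ds.n_answered,
                    "n_items": ds.n_items,
                }
            )
    return pd.DataFrame(rows)
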