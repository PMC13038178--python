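"""Pre/post outcome analysis: Wilcoxon signed-rank tests, engagement-outcome
correlations, stratified and subgroup comparisons, and the single-proportion
sample-size formula with finite-population correction.

All tests are two-sided. Analyses are complete-case: a participant missing
either the pre or the post score of a scale is dropped for that scale.
No multiplicity adjustment is applied — the stratified and subgroup
comparisons are exploratory and their outputs are flagged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "wilcoxon_signed_rank",
    "paired_change_table",
    "score_changes",
    "engagement_outcome_correlation",
    "subgroup_compare",
    "sample_size_proportion",
]


@dataclass(frozen=True)
class PairedTestResult:
    scale: str
    group: str
    n_pairs: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    statistic: float  # W+ : rank sum of positive differences
    p_value: float
    method: str  # "exact" | "approx" | "degenerate"
    n_nonzero: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    outcome: str
    r: float
    p_value: float
    n: int
    method: str


def _describe(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else float("nan")


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float],
                         zero_method: str = "discard", mode: str = "auto",
                         scale: str = "", group: str = "") -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    Zero differences are discarded by default (classical Wilcoxon); the
    Pratt variant keeps them in the ranking. In ``auto`` mode the exact
    null distribution is used when there are at most 25 nonzero
    differences with no tied absolute values (and, for the discard rule,
    after zeros are removed); otherwise the normal approximation with tie
    and continuity corrections is used. The reported statistic is W+, the
    rank sum of positive differences.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"pre/post length mismatch: {pre.shape} vs {post.shape}")
    if pre.size == 0:
        raise ValueError("no pairs supplied")
    if zero_method not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    d = post - pre
    mean_pre, sd_pre = _describe(pre)
    mean_post, sd_post = _describe(post)
    nz = d[d != 0]
    if nz.size == 0:
        return PairedTestResult(scale, group, pre.size, mean_pre, sd_pre, mean_post,
                                sd_post, float("nan"), 1.0, "degenerate", 0, degenerate=True)

    if zero_method == "discard":
        ranked = np.abs(nz)
        ranks = stats.rankdata(ranked)
        w_plus = float(ranks[nz > 0].sum())
    else:  # pratt: rank |d| including zeros, then drop the zero ranks
        ranks_all = stats.rankdata(np.abs(d))
        w_plus = float(ranks_all[d > 0].sum())

    has_ties = np.unique(np.abs(nz)).size < nz.size
    if mode == "auto":
        method = "exact" if (nz.size <= 25 and not has_ties
                             and (zero_method == "discard" or nz.size == d.size)) else "approx"
    elif mode in ("exact", "approx"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")

    scipy_zero = "wilcox" if zero_method == "discard" else "pratt"
    res = stats.wilcoxon(d, zero_method=scipy_zero, correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return PairedTestResult(scale, group, pre.size, mean_pre, sd_pre, mean_post, sd_post,
                            w_plus, float(res.pvalue), method, int(nz.size))


def _result_row(r: PairedTestResult, exploratory: bool = False) -> dict:
    row = {
        "scale": r.scale, "group": r.group, "n_pairs": r.n_pairs,
        "mean_pre": r.mean_pre, "sd_pre": r.sd_pre,
        "mean_post": r.mean_post, "sd_post": r.sd_post,
        "statistic": r.statistic, "p_value": r.p_value,
        "method": r.method, "n_nonzero": r.n_nonzero, "degenerate": r.degenerate,
    }
    if exploratory:
        row["exploratory"] = True
    return row


def _empty_row(scale: str, group: str, exploratory: bool = False) -> dict:
    return _result_row(
        PairedTestResult(scale, group, 0, float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), float("nan"), "none", 0, True),
        exploratory,
    )


def _paired_wide(scores: pd.DataFrame, scale: str) -> pd.DataFrame:
    sub = scores[scores["scale"] == scale]
    wide = sub.pivot_table(index="participant_id", columns="timepoint", values="score",
                           aggfunc="first", dropna=False)
    if "pre" not in wide.columns or "post" not in wide.columns:
        return pd.DataFrame(columns=["pre", "post"])
    return wide[["pre", "post"]].dropna()


def paired_change_table(scores: pd.DataFrame, scales: Sequence[str] | None = None,
                        groups: pd.Series | None = None, zero_method: str = "discard",
                        mode: str = "auto", exploratory: bool = False) -> pd.DataFrame:
    """Wilcoxon pre/post comparison per scale (and per stratum if supplied).

    ``scores`` is the long scores table (participant_id, timepoint, scale,
    score). Complete cases only: participants lacking either timepoint are
    dropped per-scale. An empty group yields a row with n=0 and missing
    statistics.
    """
    if scales is None:
        scales = list(pd.unique(scores["scale"]))
    rows = []
    for scale in scales:
        wide = _paired_wide(scores, scale)
        if groups is None:
            if wide.empty:
                rows.append(_empty_row(scale, "all", exploratory))
            else:
                rows.append(_result_row(
                    wilcoxon_signed_rank(wide["pre"], wide["post"], zero_method, mode,
                                         scale=scale, group="all"), exploratory))
            continue
        for label in sorted(pd.unique(groups.dropna())):
            members = groups.index[groups == label]
            sub = wide.loc[wide.index.intersection(members)]
            if sub.empty:
                rows.append(_empty_row(scale, str(label), exploratory))
            else:
                rows.append(_result_row(
                    wilcoxon_signed_rank(sub["pre"], sub["post"], zero_method, mode,
                                         scale=scale, group=str(label)), exploratory))
    return pd.DataFrame(rows)


def score_changes(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-participant post - pre change for every scale (wide; NaN where
    either timepoint is missing)."""
    wide = scores.pivot_table(index="participant_id", columns=["scale", "timepoint"],
                              values="score", aggfunc="first", dropna=False)
    scales = sorted({s for s, _ in wide.columns})
    out = {}
    for s in scales:
        if (s, "pre") in wide.columns and (s, "post") in wide.columns:
            out[s] = wide[(s, "post")] - wide[(s, "pre")]
    return pd.DataFrame(out)


def engagement_outcome_correlation(profiles: pd.DataFrame, changes: pd.DataFrame,
                                   metric: str = "total_usage_min",
                                   outcome: str = "moderation",
                                   method: str = "spearman") -> CorrelationResult:
    """Correlation between an engagement metric and a scale's pre-to-post
    change (Spearman by default; Pearson selectable). Requires >= 3
    complete pairs."""
    x = profiles.set_index("participant_id")[metric]
    y = changes[outcome]
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(joined)}")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    if method == "spearman":
        r, p = stats.spearmanr(a, b)
    elif method == "pearson":
        r, p = stats.pearsonr(a, b)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(metric, outcome, float(r), float(p), len(joined), method)


def subgroup_compare(scores: pd.DataFrame, participants: pd.DataFrame, by: str,
                     age_threshold: float = 60.0, custom: pd.Series | None = None,
                     zero_method: str = "discard", mode: str = "auto") -> pd.DataFrame:
    """Per-subgroup paired tests by demographic grouping.

    ``by`` is one of ``age`` (dichotomized at an inclusive threshold,
    default >= 60), ``sex``, ``cancer_type`` or ``custom`` (with a
    participant-indexed label series). Outputs carry an ``exploratory``
    flag; no multiplicity adjustment is applied.
    """
    part = participants.set_index("participant_id")
    if by == "age":
        groups = pd.Series(
            np.where(part["age"] >= age_threshold,
                     f"age_ge_{age_threshold:g}", f"age_lt_{age_threshold:g}"),
            index=part.index)
    elif by in ("sex", "cancer_type"):
        groups = part[by].astype(str)
    elif by == "custom":
        if custom is None:
            raise ValueError("custom grouping requires a label series")
        groups = custom
    else:
        raise ValueError(f"unknown grouping {by!r}")
    if groups.isna().any():
        missing = sorted(groups.index[groups.isna()])
        raise ValueError(f"grouping undefined for participants: {missing}")
    return paired_change_table(scores, groups=groups, zero_method=zero_method,
                               mode=mode, exploratory=True)


def sample_size_proportion(confidence: float = 0.90, margin: float = 0.10,
                           p: float = 0.5, population: int | None = None) -> int:
    """Required n for a single-proportion estimate at a given two-sided
    confidence level and margin of error, with finite-population correction.

    ``n0 = z^2 p (1-p) / e^2``; for a finite population of size N,
    ``n = n0 / (1 + (n0 - 1) / N)``. The result is rounded up.
    """
    if not 0 < margin < 1:
        raise ValueError("margin of error must be in (0, 1)")
    if not 0 < p < 1:
        raise ValueError("assumed proportion must be in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    n0 = z * z * p * (1 - p) / (margin * margin)
    if population is not None:
        if population < 1:
            raise ValueError("population size must be positive")
        n0 = n0 / (1 + (n0 - 1) / population)
    return math.ceil(n0)
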