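"""Paired testing, correlations, subgroups and the sample-size formula."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mhengage.analysis import (
    engagement_outcome_correlation,
    paired_change_table,
    sample_size_proportion,
    score_changes,
    subgroup_compare,
    wilcoxon_signed_rank,
)


def exact_wilcoxon_p(diffs):
    """Independent oracle: full enumeration of all 2^n sign assignments of
    the ranked absolute differences; two-sided p = 2*min(P(W+<=w), P(W+>=w))."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(d))]
    ws = np.array(ws)
    total = ws.size
    p = 2 * min((ws <= w_obs + 1e-9).sum(), (ws >= w_obs - 1e-9).sum()) / total
    return min(1.0, p)


def scores_frame(pre, post, scale="moderation"):
    rows = []
    for i, (a, b) in enumerate(zip(pre, post)):
        rows.append({"participant_id": f"p{i}", "timepoint": "pre", "scale": scale, "score": a})
        rows.append({"participant_id": f"p{i}", "timepoint": "post", "scale": scale, "score": b})
    return pd.DataFrame(rows)


class TestWilcoxon:
    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)
        assert res.method == "exact"

    def test_degenerate_all_zero(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate and res.p_value == 1.0 and res.n_nonzero == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])

    def test_exact_p_matches_enumeration(self, rng):
        for n in range(2, 11):
            for _ in range(25):
                pre = rng.normal(size=n)
                post = pre + rng.normal(size=n)
                res = wilcoxon_signed_rank(pre, post, mode="exact")
                assert res.p_value == pytest.approx(exact_wilcoxon_p(post - pre), abs=1e-12)

    def test_statistic_bounds_invariant(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 15))
            pre, post = rng.normal(size=n), rng.normal(size=n)
            res = wilcoxon_signed_rank(pre, post)
            assert 0 <= res.p_value <= 1
            assert res.n_nonzero <= res.n_pairs
            assert res.statistic <= res.n_nonzero * (res.n_nonzero + 1) / 2 + 1e-9

    def test_approx_close_to_exact_at_n25(self, rng):
        for _ in range(200):
            pre = rng.normal(size=25)
            post = pre + rng.normal(size=25)
            pe = wilcoxon_signed_rank(pre, post, mode="exact").p_value
            pa = wilcoxon_signed_rank(pre, post, mode="approx").p_value
            assert abs(pe - pa) < 0.02

    def test_auto_switches_to_approx_for_large_n(self, rng):
        pre = rng.normal(size=40)
        post = pre + rng.normal(size=40)
        assert wilcoxon_signed_rank(pre, post).method == "approx"

    def test_pratt_keeps_zero_ranks(self):
        pre = np.array([0.0, 0, 0, 0])
        post = np.array([0.0, 1, 2, 3])
        res_discard = wilcoxon_signed_rank(pre, post, zero_method="discard")
        res_pratt = wilcoxon_signed_rank(pre, post, zero_method="pratt")
        assert res_pratt.statistic == 2 + 3 + 4  # zeros occupy rank 1
        assert res_discard.statistic == 6.0


class TestPairedChangeTable:
    def test_single_scale_single_row(self):
        table = paired_change_table(scores_frame([1, 2, 3], [2, 3, 4]))
        assert len(table) == 1 and table["group"].iloc[0] == "all"
        assert table["n_pairs"].iloc[0] == 3

    def test_stratified_bookkeeping(self, rng):
        pre = rng.normal(70, 10, 24)
        post = pre + rng.normal(0, 5, 24)
        scores = scores_frame(pre, post)
        groups = pd.Series(["a"] * 12 + ["b"] * 12,
                           index=[f"p{i}" for i in range(24)])
        table = paired_change_table(scores, groups=groups)
        assert len(table) == 2
        assert table["n_pairs"].tolist() == [12, 12]

    def test_incomplete_pairs_dropped(self):
        scores = scores_frame([1, 2, 3], [2, 3, 4])
        scores = scores[~((scores["participant_id"] == "p2")
                          & (scores["timepoint"] == "post"))]
        table = paired_change_table(scores)
        assert table["n_pairs"].iloc[0] == 2

    def test_empty_group_row(self):
        scores = scores_frame([1, 2], [2, 3])
        groups = pd.Series(["a", "a"], index=["p0", "p1"])
        groups["ghost"] = "b"
        table = paired_change_table(scores, groups=groups)
        row_b = table[table["group"] == "b"].iloc[0]
        assert row_b["n_pairs"] == 0 and np.isnan(row_b["p_value"])


class TestCorrelation:
    def make_inputs(self, usage, change):
        profiles = pd.DataFrame({"participant_id": [f"p{i}" for i in range(len(usage))],
                                 "total_usage_min": usage})
        changes = pd.DataFrame({"moderation": change},
                               index=[f"p{i}" for i in range(len(change))])
        return profiles, changes

    def test_perfect_monotone(self):
        profiles, changes = self.make_inputs([1, 2, 3, 4], [10, 20, 30, 40])
        res = engagement_outcome_correlation(profiles, changes)
        assert res.r == pytest.approx(1.0)

    def test_perfect_antitone(self):
        profiles, changes = self.make_inputs([1, 2, 3, 4], [4, 3, 2, 1])
        assert engagement_outcome_correlation(profiles, changes).r == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        profiles, changes = self.make_inputs([1, 2], [1, 2])
        with pytest.raises(ValueError, match="3 complete pairs"):
            engagement_outcome_correlation(profiles, changes)

    def test_pearson_selectable(self):
        profiles, changes = self.make_inputs([1.0, 2, 3, 4], [2.0, 4, 6, 8])
        res = engagement_outcome_correlation(profiles, changes, method="pearson")
        assert res.method == "pearson" and res.r == pytest.approx(1.0)


class TestSubgroups:
    def participants(self, ages):
        return pd.DataFrame({"participant_id": [f"p{i}" for i in range(len(ages))],
                             "age": ages, "sex": ["F"] * len(ages),
                             "cancer_type": ["breast"] * len(ages)})

    def test_single_subgroup_matches_ungrouped(self, rng):
        pre = rng.normal(70, 10, 10)
        post = pre + rng.normal(0, 5, 10)
        scores = scores_frame(pre, post)
        grouped = subgroup_compare(scores, self.participants([50] * 10), by="age")
        plain = paired_change_table(scores)
        assert grouped["p_value"].iloc[0] == pytest.approx(plain["p_value"].iloc[0])
        assert bool(grouped["exploratory"].iloc[0])

    def test_age_threshold_inclusive(self):
        scores = scores_frame([1, 2, 3], [2, 3, 4])
        table = subgroup_compare(scores, self.participants([59, 60, 61]), by="age")
        sizes = table.set_index("group")["n_pairs"]
        assert sizes["age_ge_60"] == 2 and sizes["age_lt_60"] == 1

    def test_unknown_grouping(self):
        with pytest.raises(ValueError, match="grouping"):
            subgroup_compare(scores_frame([1], [2]), self.participants([50]), by="shoe_size")


class TestSampleSize:
    def test_classic_95ci(self):
        assert sample_size_proportion(0.95, 0.10, 0.5) == 97

    def test_finite_population_feasibility_case(self):
        assert sample_size_proportion(0.90, 0.10, 0.5, population=2153) == 66

    def test_p_half_maximizes_n(self):
        n_half = sample_size_proportion(0.95, 0.05, 0.5)
        for p in (0.1, 0.3, 0.42, 0.7, 0.9):
            assert sample_size_proportion(0.95, 0.05, p) <= n_half

    def test_monotone_in_margin_and_confidence(self):
        assert sample_size_proportion(0.95, 0.05) >= sample_size_proportion(0.95, 0.10)
        assert sample_size_proportion(0.99, 0.10) >= sample_size_proportion(0.90, 0.10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_size_proportion(0.95, 0.0)
        with pytest.raises(ValueError):
            sample_size_proportion(0.95, 0.1, p=1.0)


def test_score_changes_complete_cases():
    scores = scores_frame([10.0, 20.0], [15.0, 30.0])
    scores.loc[(scores["participant_id"] == "p1")
               & (scores["timepoint"] == "post"), "score"] = np.nan
    changes = score_changes(scores)
    assert changes.loc["p0", "moderation"] == pytest.approx(5.0)
    assert np.isnan(changes.loc["p1", "moderation"])
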