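"""Synthetic cohort generator: determinism, structure, ground-truth
recoverability and outcome coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mhengage.scoring import NQ2021, QLQC30, load_nq2021_spec, load_qlqc30_spec, score_form
from mhengage.sessions import sessionize_all
from mhengage.simulate import SimConfig, generate_cohort, generate_event_log, generate_item_responses


def cfg(**kw):
    base = dict(n_participants=6, seed=42, events_per_session_mean=6.0)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = generate_cohort(cfg())
        b = generate_cohort(cfg())
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.forms, b.forms)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = generate_cohort(cfg())
        b = generate_cohort(cfg(seed=43))
        assert not a.events.equals(b.events)


class TestCohortStructure:
    def test_no_dropout_means_all_post_forms(self):
        cohort = generate_cohort(cfg(dropout_hazard_per_day=0.0))
        post = cohort.forms[cohort.forms["timepoint"] == "post"]
        assert post["participant_id"].nunique() == 6
        assert cohort.participants["completed"].all()

    def test_every_participant_has_pre_forms(self):
        cohort = generate_cohort(cfg(dropout_hazard_per_day=0.2, seed=5))
        pre = cohort.forms[cohort.forms["timepoint"] == "pre"]
        assert pre["participant_id"].nunique() == 6

    def test_early_dropouts_have_no_post_forms(self):
        cohort = generate_cohort(cfg(dropout_hazard_per_day=0.2, seed=5))
        early = cohort.truth[cohort.truth["dropout_day"].notna()
                             & (cohort.truth["dropout_day"] <= 14)]
        assert len(early) > 0  # hazard 0.2 makes early dropout near-certain
        post_ids = set(cohort.forms.loc[cohort.forms["timepoint"] == "post", "participant_id"])
        assert post_ids.isdisjoint(early["participant_id"])

    def test_events_inside_enrollment_window(self):
        cohort = generate_cohort(cfg())
        enr = cohort.enrollment
        start = cohort.events["participant_id"].map(enr)
        rel_days = (cohort.events["timestamp"] - start) / pd.Timedelta(days=1)
        assert ((rel_days >= 0) & (rel_days < 28)).all()

    def test_no_events_after_dropout_day(self):
        cohort = generate_cohort(cfg(dropout_hazard_per_day=0.2, seed=5))
        truth = cohort.truth.set_index("participant_id")
        for pid, grp in cohort.events.groupby("participant_id"):
            d = truth.loc[pid, "dropout_day"]
            if pd.isna(d):
                continue
            last = (grp["timestamp"].max() - cohort.enrollment[pid]) / pd.Timedelta(days=1)
            assert last < d  # app use stops with the dropout day

    def test_invalid_config_names_field(self):
        with pytest.raises(Exception, match="dropout_hazard_per_day"):
            SimConfig(dropout_hazard_per_day=1.5)
        with pytest.raises(Exception, match="meal_anchors"):
            SimConfig(meal_anchors=[25.0])


class TestEventLog:
    def test_zero_propensity_empty(self):
        rng = np.random.default_rng(0)
        events, sessions = generate_event_log(0.0, pd.Timestamp("2024-10-01", tz="UTC"), 28, rng)
        assert events.empty and sessions.empty

    def test_negative_propensity_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="propensity"):
            generate_event_log(-1.0, pd.Timestamp("2024-10-01", tz="UTC"), 28, rng)

    def test_timestamps_nondecreasing(self):
        rng = np.random.default_rng(1)
        events, _ = generate_event_log(3.0, pd.Timestamp("2024-10-01", tz="UTC"), 28, rng)
        assert events["timestamp"].is_monotonic_increasing

    def test_daily_session_count_is_poisson(self):
        # mean of Poisson(2.3) daily counts over many days
        rng = np.random.default_rng(2)
        _, sessions = generate_event_log(2.3, pd.Timestamp("2024-10-01", tz="UTC"), 400, rng)
        per_day = len(sessions) / 400
        assert per_day == pytest.approx(2.3, abs=3 * np.sqrt(2.3 / 400))

    def test_ground_truth_sessions_recoverable(self, small_cohort):
        recovered = sessionize_all(small_cohort.events, small_cohort.config.session_gap_min)
        by_pid = recovered.groupby("participant_id").size()
        truth = small_cohort.truth.set_index("participant_id")["n_true_sessions"]
        for pid in truth.index:
            assert by_pid.get(pid, 0) == truth[pid]


class TestItemResponseInversion:
    def test_functional_target_100_gives_best_responses(self):
        form = generate_item_responses({"physical_functioning": 100.0}, QLQC30, "p", "pre")
        assert all(form.responses[i] == 1 for i in ("q1", "q2", "q3", "q4", "q5"))

    def test_symptom_target_0_gives_best_responses(self):
        form = generate_item_responses({"fatigue": 0.0}, QLQC30, "p", "pre")
        assert all(form.responses[i] == 1 for i in ("q10", "q12", "q18"))

    def test_worked_example_physical_8667(self):
        form = generate_item_responses({"physical_functioning": 86.67}, QLQC30, "p", "pre")
        scored = {d.scale: d.score for d in score_form(form)}
        # quantization step for a 5-item range-3 scale: 100/15
        assert scored["physical_functioning"] == pytest.approx(86.67, abs=100 / 15)
        responses = [form.responses[f"q{i}"] for i in range(1, 6)]
        assert np.mean(responses) == pytest.approx(1.4)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="physical_functioning"):
            generate_item_responses({"physical_functioning": 120.0}, QLQC30, "p", "pre")

    @pytest.mark.parametrize("instrument", [QLQC30, NQ2021])
    def test_round_trip_within_quantization(self, instrument, rng):
        spec = load_qlqc30_spec() if instrument == QLQC30 else load_nq2021_spec()
        spans = {s.name: (len(s.items), s.item_range if instrument == QLQC30 else
                          sum(spec.item_ranges[i][1] - spec.item_ranges[i][0] for i in s.items)
                          / len(s.items))
                 for s in spec.scales}
        for _ in range(1000):
            targets = {s.name: float(rng.uniform(0, 100)) for s in spec.scales}
            form = generate_item_responses(targets, instrument, "p", "pre")
            scored = {d.scale: d.score for d in score_form(form)}
            for name, t in targets.items():
                k, span = spans[name]
                step = 100.0 / (k * span)
                assert abs(scored[name] - t) <= step / 2 + 1e-9, (name, t, scored[name])


class TestOutcomeCoupling:
    def test_null_coupling_changes_centered_at_zero(self):
        c = SimConfig(n_participants=500, seed=9, dropout_hazard_per_day=0.0,
                      events_per_session_mean=3.0, outcome_coupling_beta={},
                      outcome_noise_sd=6.0)
        cohort = generate_cohort(c)
        from mhengage.analysis import score_changes
        from mhengage.scoring import score_forms
        changes = score_changes(score_forms(cohort.forms))
        for scale in ("moderation", "global_health", "physical_functioning"):
            ch = changes[scale].dropna()
            se = ch.std(ddof=1) / np.sqrt(len(ch))
            assert abs(ch.mean()) <= 3 * se

    def test_coupling_recovers_oracle_rank_correlation(self):
        beta, noise = 4.84, 8.0
        c = SimConfig(n_participants=500, seed=10, dropout_hazard_per_day=0.0,
                      events_per_session_mean=3.0,
                      outcome_coupling_beta={"moderation": beta},
                      outcome_noise_sd=noise)
        cohort = generate_cohort(c)
        from mhengage.analysis import score_changes
        from mhengage.scoring import score_forms
        changes = score_changes(score_forms(cohort.forms))
        z = cohort.truth.set_index("participant_id")["engagement_z"]
        r = stats.spearmanr(z, changes.loc[z.index, "moderation"]).statistic

        # Monte-Carlo oracle on the generator's latent model
        orng = np.random.default_rng(123)
        zs = orng.normal(size=100_000)
        implied = stats.spearmanr(zs, beta * zs + orng.normal(0, noise, zs.size)).statistic
        assert r == pytest.approx(implied, abs=0.1)
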