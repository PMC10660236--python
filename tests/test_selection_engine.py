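"""Selection rules: habituation, anti-repetition, tiers, rescue, determinism."""

import re

import numpy as np
import pytest

from weeklycoach.domain_model import (
    Domain,
    MessageKind,
    Milestone,
    ParticipantHistory,
    SelectionAudit,
    WeeklyVariables,
    WeightCategory,
)
from weeklycoach.message_bank import MessageBank, ProgressTier, TargetedSlot
from weeklycoach.renderer import render_message
from weeklycoach.selection_engine import (
    compose_week,
    derive_progress_tier,
    derive_rng_seed,
    select_parent,
    select_targeted,
    select_theme,
    select_weight_feedback,
)
from weeklycoach.weekly_aggregation import WeekWindow
from weeklycoach.synthetic_cohort import make_scenario

from conftest import PROGRAM_START, bank_dict, make_bank


def make_vars(**kw) -> WeeklyVariables:
    base = dict(
        week_index=5, weight_change=-1.0,
        weight_category=WeightCategory.LOSS, cum_pct_change=-3.0,
        days_self_weighed=7, mvpa_minutes=120.0, activity_tracking_days=6,
        avg_calorie_intake=1650.0, days_in_range=4, days_above_range=1,
        days_below_range=1, monitoring_days=5, app_used=True,
        trailing3_net_change=-1.0,
        trailing3_categories=[WeightCategory.LOSS, WeightCategory.LOSS,
                              WeightCategory.MAINTENANCE])
    base.update(kw)
    return WeeklyVariables(**base)


def fresh(pid="p1"):
    return ParticipantHistory(participant_id=pid)


def audit():
    return SelectionAudit(rng_seed=0)


class TestWeightFeedback:
    def test_no_weigh_week_gets_reminder(self, minimal_bank, profile):
        vars_ = make_vars(days_self_weighed=0, weight_change=None,
                          weight_category=WeightCategory.UNKNOWN,
                          cum_pct_change=None)
        a = audit()
        fb = select_weight_feedback(vars_, profile, fresh(), minimal_bank,
                                    np.random.default_rng(0), a)
        assert fb.kind == "reminder"
        assert fb.text == minimal_bank.no_weigh_reminder
        assert a.stage("weight").fallback

    def test_different_message_each_time_until_exhausted(self, minimal_bank,
                                                         profile):
        """Two-message signature: first two sends differ, third reuses the
        id sent longest ago (least-recently-used reset)."""
        hist = fresh()
        rng = np.random.default_rng(5)
        sent = []
        for _ in range(3):
            fb = select_weight_feedback(make_vars(), profile, hist,
                                        minimal_bank, rng, audit())
            sent.append(fb.message_id)
        assert sent[0] != sent[1]
        assert sent[2] == sent[0]  # LRU: the earliest-sent id returns first

    def test_lru_reset_over_all_send_orders(self, minimal_bank, profile):
        """Whatever order the first cycle took, the reset replays it."""
        for seed in range(10):
            hist = fresh()
            rng = np.random.default_rng(seed)
            sent = [select_weight_feedback(make_vars(), profile, hist,
                                           minimal_bank, rng,
                                           audit()).message_id
                    for _ in range(4)]
            assert sent[2] == sent[0] and sent[3] == sent[1]

    def test_milestone_prepended_once(self, minimal_bank, profile):
        hist = fresh()
        rng = np.random.default_rng(0)
        fb1 = select_weight_feedback(make_vars(cum_pct_change=-5.2), profile,
                                     hist, minimal_bank, rng, audit())
        assert fb1.milestone_texts == [minimal_bank.milestone_texts[
            Milestone.FIVE_PCT]]
        assert hist.milestones_reached == {Milestone.FIVE_PCT}
        fb2 = select_weight_feedback(make_vars(cum_pct_change=-5.4), profile,
                                     hist, minimal_bank, rng, audit())
        assert fb2.milestone_texts == []

    def test_signatures_tracked_separately(self, minimal_bank, profile):
        hist = fresh()
        rng = np.random.default_rng(1)
        select_weight_feedback(make_vars(), profile, hist, minimal_bank, rng,
                               audit())
        gain = make_vars(weight_change=1.0,
                         weight_category=WeightCategory.GAIN)
        select_weight_feedback(gain, profile, hist, minimal_bank, rng, audit())
        assert len(hist.sent_weight_message_ids) == 2


class TestProgressTier:
    @pytest.mark.parametrize("category,trailing,expected", [
        (WeightCategory.GAIN, 1.2, ProgressTier.DECLINING),
        (WeightCategory.GAIN, None, ProgressTier.DECLINING),
        (WeightCategory.MAINTENANCE, 1.2, ProgressTier.DECLINING),
        (WeightCategory.LOSS, -2.0, ProgressTier.IMPROVING),
        (WeightCategory.LOSS, 0.0, ProgressTier.FLAT),
        (WeightCategory.LOSS, None, ProgressTier.FLAT),
        (WeightCategory.MAINTENANCE, -0.2, ProgressTier.FLAT),
        (WeightCategory.UNKNOWN, None, ProgressTier.FLAT),
        (WeightCategory.UNKNOWN, 2.0, ProgressTier.FLAT),  # no data, no tier
    ])
    def test_tier_rules(self, category, trailing, expected):
        vars_ = make_vars(
            weight_change=None if category == WeightCategory.UNKNOWN else
            {"LOSS": -1.0, "MAINTENANCE": 0.0, "GAIN": 1.0}[category.value],
            weight_category=category, trailing3_net_change=trailing)
        assert derive_progress_tier(vars_) == expected


class TestSelectTheme:
    def test_consecutive_theme_forced_out(self, minimal_bank):
        for seed in range(20):
            hist = ParticipantHistory(participant_id="x", last_theme="alpha")
            a = audit()
            chosen = select_theme(ProgressTier.FLAT, hist, minimal_bank,
                                  np.random.default_rng(seed), a)
            assert chosen == "beta"
            assert a.stage("theme").excluded == {"alpha": "consecutive-theme"}

    def test_zero_weight_theme_never_chosen(self):
        bank = make_bank(themes=[
            {"id": "a", "label": "A", "weights":
                {"DECLINING": 0.0, "FLAT": 0.5, "IMPROVING": 0.5}},
            {"id": "b", "label": "B", "weights":
                {"DECLINING": 0.5, "FLAT": 0.5, "IMPROVING": 0.5}},
            {"id": "c", "label": "C", "weights":
                {"DECLINING": 0.5, "FLAT": 0.5, "IMPROVING": 0.5}},
        ], parent_messages=[
            {"id": f"p{t}", "theme_id": t, "domain": "APP_USE",
             "criteria": [], "text": "x.", "is_fallback": True}
            for t in ("a", "b", "c")])
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert select_theme(ProgressTier.DECLINING, fresh(), bank, rng,
                                audit()) != "a"


class TestSelectParent:
    def test_domain_repeat_forced_out(self, profile):
        bank = make_bank(parent_messages=[
            {"id": "p-weigh", "theme_id": "alpha", "domain": "SELF_WEIGHING",
             "criteria": [], "text": "w.", "is_fallback": True},
            {"id": "p-act", "theme_id": "alpha", "domain": "PHYSICAL_ACTIVITY",
             "criteria": [], "text": "a.", "is_fallback": True},
            {"id": "pb", "theme_id": "beta", "domain": "APP_USE",
             "criteria": [], "text": "b.", "is_fallback": True},
        ])
        hist = fresh()
        hist.last_parent_domain = Domain.SELF_WEIGHING
        for seed in range(20):
            a = audit()
            p = select_parent(make_vars(), profile, "alpha", hist, bank,
                              np.random.default_rng(seed), a)
            assert p.id == "p-act"
            assert a.stage("parent").excluded["p-weigh"] == "domain-repeat"
            hist.last_parent_domain = Domain.SELF_WEIGHING  # reset

    def test_fallback_chosen_when_nothing_else_matches(self, profile):
        bank = make_bank(parent_messages=[
            {"id": "p-cond", "theme_id": "alpha", "domain": "SELF_WEIGHING",
             "criteria": [{"var": "days_self_weighed", "op": "EQ", "value": 0}],
             "text": "w."},
            {"id": "p-fall", "theme_id": "alpha", "domain": "APP_USE",
             "criteria": [], "text": "f.", "is_fallback": True},
            {"id": "pb", "theme_id": "beta", "domain": "APP_USE",
             "criteria": [], "text": "b.", "is_fallback": True},
        ])
        a = audit()
        p = select_parent(make_vars(), profile, "alpha", fresh(), bank,
                          np.random.default_rng(0), a)
        assert p.id == "p-fall"
        assert a.stage("parent").excluded["p-cond"] == "criteria-fail"

    def test_last_resort_domain_repeat_is_audited(self, profile):
        bank = make_bank(parent_messages=[
            {"id": "pa", "theme_id": "alpha", "domain": "APP_USE",
             "criteria": [], "text": "x.", "is_fallback": True},
            {"id": "pb", "theme_id": "beta", "domain": "APP_USE",
             "criteria": [], "text": "y.", "is_fallback": True},
        ])
        hist = fresh()
        hist.last_parent_domain = Domain.APP_USE
        a = audit()
        p = select_parent(make_vars(), profile, "alpha", hist, bank,
                          np.random.default_rng(0), a)
        assert p.id == "pa"
        assert a.stage("parent").fallback
        assert "repeat permitted" in a.stage("parent").notes


class TestSelectTargeted:
    def test_slot_none_yields_none(self, minimal_bank):
        parent = minimal_bank.parent_messages[0]
        assert parent.targeted_slot == TargetedSlot.NONE
        assert select_targeted(parent, minimal_bank,
                               np.random.default_rng(0), audit()) is None

    def test_domain_and_type_matched(self, default_bank):
        parent = next(p for p in default_bank.parent_messages
                      if p.targeted_slot == TargetedSlot.STRATEGY
                      and p.domain == Domain.SELF_WEIGHING)
        rng = np.random.default_rng(0)
        seen = {select_targeted(parent, default_bank, rng, audit()).id
                for _ in range(50)}
        pool = {m.id for m in default_bank.targeted_for(
            Domain.SELF_WEIGHING, TargetedSlot.STRATEGY)}
        assert seen == pool  # only, and eventually all, matching messages


class TestComposeWeek:
    def test_same_inputs_same_seed_byte_identical(self, default_bank):
        records, profile = make_scenario("steady_loser")
        outs = []
        for _ in range(2):
            hist = fresh(profile.participant_id)
            texts = []
            for k in range(1, 9):
                msg = compose_week(records,
                                   WeekWindow.for_week(PROGRAM_START, k),
                                   profile, hist, default_bank, 42)
                texts.append(render_message(msg))
                texts.append(msg.audit.model_dump_json())
            outs.append("\n".join(texts))
        assert outs[0] == outs[1]

    def test_rescue_message_has_no_numerals(self, default_bank):
        records, profile = make_scenario("rescue")
        hist = fresh(profile.participant_id)
        for k in range(1, 5):
            msg = compose_week(records, WeekWindow.for_week(PROGRAM_START, k),
                               profile, hist, default_bank, 7)
            assert msg.kind == MessageKind.RESCUE_CHECKIN
            text = render_message(msg)
            assert not re.search(r"\d", text)
            assert msg.summary_box is None
            assert msg.weight_component is None
            assert msg.behavioral_component is None

    def test_rescue_texts_rotate(self, default_bank):
        records, profile = make_scenario("rescue")
        hist = fresh(profile.participant_id)
        texts = [compose_week(records, WeekWindow.for_week(PROGRAM_START, k),
                              profile, hist, default_bank, 7).checkin_text
                 for k in range(1, 4)]
        assert len(set(texts)) == len(default_bank.rescue_checkin_texts)

    def test_trajectory_never_repeats_theme_or_domain(self, default_bank):
        """52 scripted weeks: consecutive themes and domains always differ."""
        records, profile = make_scenario("perfect_adherence")
        hist = fresh(profile.participant_id)
        themes, domains = [], []
        for k in range(1, 53):
            msg = compose_week(records, WeekWindow.for_week(PROGRAM_START, k),
                               profile, hist, default_bank, 11)
            b = msg.behavioral_component
            themes.append(b.theme_id)
            domains.append(b.domain)
        assert all(a != b for a, b in zip(themes, themes[1:]))
        assert all(a != b for a, b in zip(domains, domains[1:]))

    def test_seed_derivation_stable_and_distinct(self):
        s = derive_rng_seed(42, "p1", 3)
        assert s == derive_rng_seed(42, "p1", 3)
        assert 0 <= s < 2 ** 31
        assert len({derive_rng_seed(42, "p1", k) for k in range(1, 20)}) == 19
        assert derive_rng_seed(42, "p1", 3) != derive_rng_seed(43, "p1", 3)
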