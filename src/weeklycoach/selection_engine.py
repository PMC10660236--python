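"""Multi-stage weekly message selection.

Given one week's tailoring variables, a participant's history and a
message bank, the engine assembles the weekly coaching message in stages:

1. weight feedback — criteria-matched bank message with habituation
   avoidance (never repeat an id at the same criteria signature until all
   alternatives are exhausted), first-time milestone prepends, and the
   self-weigh reminder on zero-weigh-in weeks;
2. progress tier — a deterministic three-level summary of recent progress;
3. theme — weighted categorical draw over the bank's themes, with the
   previous week's theme excluded;
4. parent subcomponent — uniform draw among criteria-matching parents of
   the theme, excluding the previous week's behavioral domain;
5. targeted feedback — uniform draw among domain-matched closers when the
   parent requests one.

Rescue mode bypasses all of it and emits a neutral check-in.  Every stage
writes a :class:`~weeklycoach.domain_model.StageAudit`, and the whole
pipeline is a pure function of (inputs, seed).
"""

from __future__ import annotations

import datetime as dt
import hashlib
from typing import Optional, Sequence

import numpy as np

from . import renderer
from .domain_model import (
    BehavioralFeedback,
    CoachingMessage,
    DailyRecord,
    Domain,
    MessageKind,
    Milestone,
    ParticipantHistory,
    ParticipantProfile,
    SelectionAudit,
    StageAudit,
    ValidationError,
    WeeklyVariables,
    WeightCategory,
    WeightFeedback,
)
from .message_bank import (
    BankError,
    MessageBank,
    ParentMessage,
    ProgressTier,
    TargetedMessage,
    TargetedSlot,
    build_state,
    match_criteria,
    signature_key,
)
from .weekly_aggregation import (
    MAINTENANCE_BAND_LBS,
    WeekWindow,
    aggregate_week,
    detect_milestones,
)

__all__ = [
    "derive_rng_seed",
    "derive_progress_tier",
    "select_weight_feedback",
    "select_theme",
    "select_parent",
    "select_targeted",
    "compose_week",
]


def derive_rng_seed(global_seed: int, participant_id: str,
                    week_index: int) -> int:
    """Stable per-participant-week RNG seed.

    Hashing (global_seed, participant_id, week_index) makes every
    participant-week an independent reproducible stream, so results do not
    depend on cohort iteration order.  SHA-256 keeps the derivation stable
    across platforms and Python processes (unlike builtin ``hash``).
    """
    digest = hashlib.sha256(
        f"{global_seed}|{participant_id}|{week_index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def derive_progress_tier(variables: WeeklyVariables) -> ProgressTier:
    """Three-level weight-loss progress summary driving theme weights.

    DECLINING when the past week was a gain or the trailing three weeks
    netted a gain; IMPROVING when the past week was a loss and the
    trailing weeks netted a loss; FLAT otherwise.  Weeks with no
    observable weight change map to FLAT — with no weight data there is no
    basis for either direction.
    """
    if variables.weight_category == WeightCategory.UNKNOWN:
        return ProgressTier.FLAT
    trailing = variables.trailing3_net_change
    if (variables.weight_category == WeightCategory.GAIN
            or (trailing is not None and trailing > MAINTENANCE_BAND_LBS)):
        return ProgressTier.DECLINING
    if (variables.weight_category == WeightCategory.LOSS
            and trailing is not None and trailing < -MAINTENANCE_BAND_LBS):
        return ProgressTier.IMPROVING
    return ProgressTier.FLAT


def _uniform_pick(ids: Sequence[str], rng: np.random.Generator) -> tuple[int, float]:
    """Uniform index draw, returning (index, raw draw) for the audit."""
    draw = float(rng.random())
    return min(int(draw * len(ids)), len(ids) - 1), draw


def select_weight_feedback(variables: WeeklyVariables,
                           profile: ParticipantProfile,
                           history: ParticipantHistory,
                           bank: MessageBank,
                           rng: np.random.Generator,
                           audit: SelectionAudit) -> WeightFeedback:
    """Choose the weight component and update the habituation history.

    Zero weigh-ins this week yields the self-weigh reminder instead of
    feedback.  Otherwise messages matching the week's criteria signature
    are gathered, ids already sent at this signature are excluded, and one
    of the remainder is drawn uniformly; once the signature's messages are
    exhausted, the least recently sent id is reused (maximizing spacing).
    First-time 5%/10% milestone texts are prepended and recorded.
    """
    stage = StageAudit(stage="weight")
    audit.stages.append(stage)

    if variables.days_self_weighed == 0:
        stage.fallback = True
        stage.notes = "no weigh-ins this week: self-weigh reminder"
        stage.chosen = "no_weigh_reminder"
        return WeightFeedback(kind="reminder", text=bank.no_weigh_reminder)

    state = build_state(variables, profile)
    sig = signature_key(state)
    stage.notes = f"signature {sig}"
    matching = [m for m in bank.weight_messages if match_criteria(m.criteria, state)]
    if not matching:
        raise BankError(
            f"no weight message matches signature {sig}; bank coverage is broken")
    stage.candidates = [m.id for m in matching]

    sent = history.sent_weight_message_ids.get(sig, [])
    fresh = [m for m in matching if m.id not in sent]
    for m in matching:
        if m.id in sent:
            stage.excluded[m.id] = "already-sent"
    if fresh:
        idx, draw = _uniform_pick([m.id for m in fresh], rng)
        chosen = fresh[idx]
        stage.random_draw = draw
    else:
        # All ids at this signature exhausted: restart with the id whose
        # last send lies furthest back, deterministically.
        chosen = min(matching, key=lambda m: max(i for i, s in enumerate(sent)
                                                 if s == m.id))
        stage.fallback = True
        stage.notes += "; signature exhausted, least-recently-sent reset"
        stage.excluded.pop(chosen.id, None)
    stage.chosen = chosen.id
    history.record_weight_send(sig, chosen.id)

    milestone_texts: list[str] = []
    if variables.cum_pct_change is not None:
        events = detect_milestones(variables.cum_pct_change, history)
        for event in sorted(events, key=lambda m: list(Milestone).index(m)):
            milestone_texts.append(bank.milestone_texts[event])
            history.milestones_reached.add(event)
        if events:
            stage.notes += ("; milestones "
                            + ",".join(sorted(e.value for e in events)))

    context = renderer.substitution_context(variables, profile)
    text = renderer.substitute(chosen.text, context, f"weight_messages[{chosen.id}]")
    return WeightFeedback(kind="message", message_id=chosen.id,
                          milestone_texts=milestone_texts, text=text)


def select_theme(tier: ProgressTier, history: ParticipantHistory,
                 bank: MessageBank, rng: np.random.Generator,
                 audit: SelectionAudit) -> str:
    """Weighted categorical theme draw, excluding last week's theme.

    The tier's weights are renormalized after zeroing the previous theme;
    bank validation guarantees at least two positive weights per tier, so
    the renormalized distribution is always proper.
    """
    stage = StageAudit(stage="theme", notes=f"tier {tier.value}")
    audit.stages.append(stage)
    weights = []
    for theme in bank.themes:
        w = theme.weights[tier]
        if theme.id == history.last_theme and w > 0:
            stage.excluded[theme.id] = "consecutive-theme"
            w = 0.0
        weights.append(w)
        if w > 0:
            stage.candidates.append(theme.id)
    total = sum(weights)
    if total <= 0:
        raise BankError(f"no usable theme weight at tier {tier.value}")
    draw = float(rng.random())
    stage.random_draw = draw
    acc = 0.0
    chosen = bank.themes[-1].id
    for theme, w in zip(bank.themes, weights):
        acc += w / total
        if draw < acc:
            chosen = theme.id
            break
    stage.chosen = chosen
    history.last_theme = chosen
    return chosen


def select_parent(variables: WeeklyVariables, profile: ParticipantProfile,
                  theme_id: str, history: ParticipantHistory,
                  bank: MessageBank, rng: np.random.Generator,
                  audit: SelectionAudit) -> ParentMessage:
    """Uniform draw among matching parents, avoiding last week's domain.

    Candidates are the theme's parents whose criteria match the weekly
    state.  Parents in the previous week's behavioral domain are excluded;
    if that empties the pool the theme's fallback parents outside the
    excluded domain step in, and only if none exists is the domain repeat
    permitted (and flagged in the audit).
    """
    stage = StageAudit(stage="parent", notes=f"theme {theme_id}")
    audit.stages.append(stage)
    state = build_state(variables, profile)
    candidates = [p for p in bank.parents_of_theme(theme_id)
                  if match_criteria(p.criteria, state)]
    for p in bank.parents_of_theme(theme_id):
        if p not in candidates:
            stage.excluded[p.id] = "criteria-fail"
    if not candidates:
        raise ValidationError(
            f"no parent message of theme {theme_id!r} matches the weekly "
            f"state — coverage hole: {state}")
    stage.candidates = [p.id for p in candidates]

    excluded_domain = history.last_parent_domain
    eligible = [p for p in candidates if p.domain != excluded_domain]
    for p in candidates:
        if p.domain == excluded_domain:
            stage.excluded[p.id] = "domain-repeat"
    if not eligible:
        fallbacks = [p for p in bank.parents_of_theme(theme_id)
                     if p.is_fallback and p.domain != excluded_domain]
        if fallbacks:
            eligible = fallbacks
            stage.fallback = True
            stage.notes += "; domain exclusion emptied pool, using fallbacks"
        else:
            eligible = candidates
            stage.fallback = True
            stage.notes += "; domain repeat permitted (no alternative)"
            for p in candidates:
                stage.excluded.pop(p.id, None)

    idx, draw = _uniform_pick([p.id for p in eligible], rng)
    chosen = eligible[idx]
    stage.random_draw = draw
    stage.chosen = chosen.id
    history.last_parent_domain = chosen.domain
    return chosen


def select_targeted(parent: ParentMessage, bank: MessageBank,
                    rng: np.random.Generator,
                    audit: SelectionAudit) -> Optional[TargetedMessage]:
    """Uniform draw of a domain-matched targeted closer, if requested."""
    stage = StageAudit(stage="targeted")
    audit.stages.append(stage)
    if parent.targeted_slot == TargetedSlot.NONE:
        stage.notes = "parent requests no targeted feedback"
        return None
    pool = bank.targeted_for(parent.domain, parent.targeted_slot)
    if not pool:
        raise BankError(
            f"no targeted message for (domain={parent.domain.value}, "
            f"type={parent.targeted_slot.value})")
    stage.candidates = [m.id for m in pool]
    idx, draw = _uniform_pick(stage.candidates, rng)
    stage.random_draw = draw
    chosen = pool[idx]
    stage.chosen = chosen.id
    return chosen


def compose_week(records: Sequence[DailyRecord], window: WeekWindow,
                 profile: ParticipantProfile, history: ParticipantHistory,
                 bank: MessageBank, global_seed: int) -> CoachingMessage:
    """Run the full weekly pipeline for one participant-week.

    In rescue mode a neutral check-in is emitted (rotating through the
    bank's check-in texts) and no data-derived feedback is exposed; the
    weekly variables are still logged internally so the week sequence
    stays contiguous if rescue mode is later switched off.  Otherwise:
    aggregate, weight feedback, tier, theme, parent, targeted, render.
    ``history`` is updated in place; the whole call is deterministic in
    (inputs, global_seed).
    """
    seed = derive_rng_seed(global_seed, profile.participant_id,
                           window.week_index)
    rng = np.random.default_rng(seed)
    audit = SelectionAudit(rng_seed=seed)

    variables = aggregate_week(records, window, profile,
                               prior_weeks=history.weekly_variables_log)
    history.weekly_variables_log.append(variables)

    if profile.rescue_mode:
        texts = bank.rescue_checkin_texts
        idx = history.rescue_weeks_seen % len(texts)
        history.rescue_weeks_seen += 1
        audit.stages.append(StageAudit(
            stage="rescue", chosen=f"rescue_checkin_texts[{idx}]",
            notes="rescue mode active: data feedback disabled"))
        message = CoachingMessage(
            participant_id=profile.participant_id,
            week_index=window.week_index,
            kind=MessageKind.RESCUE_CHECKIN,
            checkin_text=texts[idx],
            audit=audit)
        history.messages_log.append(message)
        return message

    weight = select_weight_feedback(variables, profile, history, bank, rng, audit)
    tier = derive_progress_tier(variables)
    theme_id = select_theme(tier, history, bank, rng, audit)
    parent = select_parent(variables, profile, theme_id, history, bank, rng, audit)
    targeted = select_targeted(parent, bank, rng, audit)

    context = renderer.substitution_context(variables, profile)
    behavioral_text = renderer.substitute(
        parent.text, context, f"parent_messages[{parent.id}]")
    if targeted is not None:
        behavioral_text += " " + renderer.substitute(
            targeted.text, context, f"targeted_messages[{targeted.id}]")

    message = CoachingMessage(
        participant_id=profile.participant_id,
        week_index=window.week_index,
        kind=MessageKind.FULL,
        summary_box=renderer.render_summary_box(variables, profile),
        weight_component=weight,
        behavioral_component=BehavioralFeedback(
            theme_id=theme_id, parent_id=parent.id, domain=parent.domain,
            targeted_id=targeted.id if targeted else None,
            text=behavioral_text),
        audit=audit)
    history.messages_log.append(message)
    return message
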