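"""Rendering of the summary box and assembly of the delivered message.

The summary box is plain text with one labeled line per field in a fixed
order (weight, calories, self-monitoring, activity).  Numbers follow the
documented rounding: percents to one decimal rounding half away from
zero, kcal and minutes to integers.  Absent fields render as placeholder
phrases, never as zero.  An optional markdown mode adds subheadings and
is off by default.
"""

from __future__ import annotations

import datetime as dt
import math
import re
from typing import Any, Mapping, Optional

from .domain_model import (
    CoachingMessage,
    MessageKind,
    ParticipantProfile,
    ValidationError,
    WeeklyVariables,
    WeightCategory,
)
from .weekly_aggregation import WeekWindow, compute_calorie_range

__all__ = [
    "RenderError",
    "round_half_away",
    "substitution_context",
    "substitute",
    "render_summary_box",
    "render_message",
    "delivery_manifest",
    "NO_WEIGH_PLACEHOLDER",
    "NO_DIET_PLACEHOLDER",
]

NO_WEIGH_PLACEHOLDER = "no weigh-ins"
NO_DIET_PLACEHOLDER = "no dietary records"

_STATUS_WORD = {
    WeightCategory.LOSS: "lost weight",
    WeightCategory.GAIN: "gained weight",
    WeightCategory.MAINTENANCE: "maintained weight",
    WeightCategory.UNKNOWN: NO_WEIGH_PLACEHOLDER,
}


class RenderError(ValidationError):
    """Raised when a template cannot be fully rendered."""


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3), unlike banker's
    rounding.  Display-only; underlying variables are never rounded."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def _fmt_int(value: float) -> str:
    return str(int(round_half_away(value, 0)))


def _fmt_pct(value: float) -> str:
    rounded = round_half_away(value, 1)
    return f"{rounded:+.1f}%"


def substitution_context(variables: WeeklyVariables,
                         profile: ParticipantProfile) -> dict[str, str]:
    """Formatted values for the whitelisted template placeholders.

    Only summary-box behavioral variables and program goals are exposed;
    weight values are deliberately not templatable.  Counts and minutes
    format as integers; an absent average intake renders as its
    placeholder phrase.
    """
    low, high = compute_calorie_range(profile.calorie_goal)
    return {
        "days_self_weighed": str(variables.days_self_weighed),
        "mvpa_minutes": _fmt_int(variables.mvpa_minutes),
        "activity_tracking_days": str(variables.activity_tracking_days),
        "avg_calorie_intake": (_fmt_int(variables.avg_calorie_intake)
                               if variables.avg_calorie_intake is not None
                               else NO_DIET_PLACEHOLDER),
        "days_in_range": str(variables.days_in_range),
        "days_above_range": str(variables.days_above_range),
        "days_below_range": str(variables.days_below_range),
        "monitoring_days": str(variables.monitoring_days),
        "calorie_goal": _fmt_int(profile.calorie_goal),
        "calorie_range_low": _fmt_int(low),
        "calorie_range_high": _fmt_int(high),
        "activity_goal": _fmt_int(profile.activity_goal),
    }


_PLACEHOLDER_RE = re.compile(r"\{([^{}]*)\}")


def substitute(text: str, context: Mapping[str, str], where: str) -> str:
    """Fill ``{placeholder}`` slots; any unresolved slot is an error."""

    def repl(match: re.Match[str]) -> str:
        name = match.group(1)
        if name not in context:
            raise RenderError(f"{where}: unresolved placeholder {{{name}}}")
        return context[name]

    return _PLACEHOLDER_RE.sub(repl, text)


def render_summary_box(variables: WeeklyVariables,
                       profile: ParticipantProfile) -> str:
    """One labeled line per summary field, fixed order, deterministic.

    Weight lines first (cumulative percent change, past-week status), then
    calories (average intake, target range, days in range), then activity
    (MVPA minutes, tracking days, weekly goal).
    """
    low, high = compute_calorie_range(profile.calorie_goal)
    cum = (NO_WEIGH_PLACEHOLDER + " this week"
           if variables.cum_pct_change is None
           else _fmt_pct(variables.cum_pct_change))
    avg = (NO_DIET_PLACEHOLDER if variables.avg_calorie_intake is None
           else f"{_fmt_int(variables.avg_calorie_intake)} kcal")
    lines = [
        f"Weight change since start: {cum}",
        f"Past week: {_STATUS_WORD[variables.weight_category]}",
        f"Average daily calories: {avg}",
        f"Target calorie range: {_fmt_int(low)}-{_fmt_int(high)} kcal",
        f"Days in calorie range: {variables.days_in_range} of 7",
        f"MVPA minutes this week: {_fmt_int(variables.mvpa_minutes)}",
        f"Activity tracking days: {variables.activity_tracking_days} of 7",
        f"Weekly activity goal: {_fmt_int(profile.activity_goal)} minutes",
    ]
    return "\n".join(lines)


def render_message(message: CoachingMessage, markdown: bool = False) -> str:
    """Assemble the delivered text from an already-composed message.

    FULL messages are summary box, blank line, weight component (milestone
    texts first), blank line, behavioral component.  Rescue check-ins are
    the check-in text alone.  Pure: re-rendering is byte-identical.  The
    markdown mode (off by default) adds subheadings.
    """
    if message.kind == MessageKind.RESCUE_CHECKIN:
        assert message.checkin_text is not None
        return message.checkin_text

    assert message.summary_box is not None
    assert message.behavioral_component is not None
    _check_resolved(message.summary_box, "summary_box")
    sections = []
    if markdown:
        sections.append("### Your week in numbers")
    sections.append(message.summary_box)
    if message.weight_component is not None:
        parts = list(message.weight_component.milestone_texts)
        parts.append(message.weight_component.text)
        body = "\n\n".join(parts)
        _check_resolved(body, message.weight_component.message_id or "reminder")
        if markdown:
            sections.append("### Your weight")
        sections.append(body)
    _check_resolved(message.behavioral_component.text,
                    message.behavioral_component.parent_id)
    if markdown:
        sections.append("### Your habits")
    sections.append(message.behavioral_component.text)
    return "\n\n".join(sections)


def _check_resolved(text: str, where: str) -> None:
    match = _PLACEHOLDER_RE.search(text)
    if match:
        raise RenderError(f"{where}: unresolved placeholder "
                          f"{{{match.group(1)}}} in rendered text")


def delivery_manifest(message: CoachingMessage, window: WeekWindow,
                      markdown: bool = False) -> dict[str, Any]:
    """Delivery record: the rendered text scheduled for noon on the
    intervention day (the day after the aggregated week closes)."""
    scheduled = dt.datetime.combine(window.end_date + dt.timedelta(days=1),
                                    dt.time(12, 0))
    return {
        "participant_id": message.participant_id,
        "week_index": message.week_index,
        "scheduled_datetime": scheduled.isoformat(),
        "kind": message.kind.value,
        "text": render_message(message, markdown=markdown),
    }
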