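"""Weekly aggregation of daily self-monitoring records.

Computes the weekly tailoring variables from raw daily records: past-week
weight change and its category, cumulative percent change from baseline,
self-weighing and activity-tracking day counts, weekly MVPA minutes,
average calorie intake and the within/above/below calorie-range day
counts, app use, and the trailing three-week trend.  Also detects the 5%
and 10% first-time weight-loss milestones.

Week windows are anchored to the participant's program start (week k
covers days ``program_start + 7(k-1) .. program_start + 7k - 1``), not to
calendar weeks.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .domain_model import (
    CumPctBand,
    DailyRecord,
    Milestone,
    ParticipantHistory,
    ParticipantProfile,
    Trailing3Summary,
    ValidationError,
    WeeklyVariables,
    WeightCategory,
)

__all__ = [
    "WeekWindow",
    "compute_calorie_range",
    "categorize_weight_change",
    "aggregate_week",
    "detect_milestones",
    "summarize_trailing3",
    "cum_pct_band",
    "weekly_variables_table",
]

#: Half-width of the weight-maintenance band, lbs. A weekly change strictly
#: below -0.4 is a loss, strictly above +0.4 a gain, the closed band in
#: between maintenance.
MAINTENANCE_BAND_LBS = 0.4

#: Width of the target calorie range below the participant's goal, kcal.
CALORIE_RANGE_WIDTH_KCAL = 300.0

#: Cumulative percent-loss thresholds at which milestones fire (compared
#: with <=, no tolerance).
MILESTONE_THRESHOLDS = {Milestone.FIVE_PCT: -5.0, Milestone.TEN_PCT: -10.0}


class WeekWindow(BaseModel):
    """A seven-day program week, inclusive of both endpoints."""

    model_config = {"frozen": True}

    start_date: dt.date
    end_date: dt.date
    week_index: int = Field(ge=1)

    @model_validator(mode="after")
    def _check_span(self) -> "WeekWindow":
        if (self.end_date - self.start_date).days != 6:
            raise ValueError("a week window spans exactly 7 consecutive days")
        return self

    @classmethod
    def for_week(cls, program_start: dt.date, week_index: int) -> "WeekWindow":
        """Window of program week ``week_index`` (1-based) from ``program_start``."""
        start = program_start + dt.timedelta(days=7 * (week_index - 1))
        return cls(start_date=start, end_date=start + dt.timedelta(days=6),
                   week_index=week_index)

    def contains(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.end_date


def compute_calorie_range(calorie_goal: float) -> tuple[float, float]:
    """Target daily calorie range: 300 kcal below the goal up to the goal.

    A day is "within range" iff ``low <= calories <= high``, both bounds
    inclusive.  Goals under 300 kcal would make the lower bound negative
    and are rejected.
    """
    if calorie_goal < CALORIE_RANGE_WIDTH_KCAL:
        raise ValidationError(
            f"calorie_goal must be >= {CALORIE_RANGE_WIDTH_KCAL:g} kcal, "
            f"got {calorie_goal:g}")
    return (calorie_goal - CALORIE_RANGE_WIDTH_KCAL, calorie_goal)


def categorize_weight_change(delta: Optional[float]) -> WeightCategory:
    """Categorize a weekly weight change in lbs.

    Loss below -0.4 lbs, gain above +0.4 lbs, maintenance the inclusive
    band between; an absent delta is UNKNOWN.  The three numeric
    categories partition the real line.
    """
    if delta is None:
        return WeightCategory.UNKNOWN
    if delta < -MAINTENANCE_BAND_LBS:
        return WeightCategory.LOSS
    if delta > MAINTENANCE_BAND_LBS:
        return WeightCategory.GAIN
    return WeightCategory.MAINTENANCE


def summarize_trailing3(categories: Sequence[WeightCategory],
                        net_change: Optional[float]) -> Trailing3Summary:
    """Collapse the trailing three weekly categories + net change to a summary.

    Weeks with UNKNOWN category are ignored.  If every observed week was a
    loss (or every one a gain) the summary is ALL_LOSS (ALL_GAIN); when
    weeks disagree the net change names the direction (MIXED_GAIN above
    +0.4 lbs, MIXED_LOSS below -0.4 lbs, FLAT otherwise).  With no
    observed weeks the summary is UNKNOWN.
    """
    observed = [c for c in categories if c != WeightCategory.UNKNOWN]
    if not observed or net_change is None:
        return Trailing3Summary.UNKNOWN
    if all(c == WeightCategory.LOSS for c in observed):
        return Trailing3Summary.ALL_LOSS
    if all(c == WeightCategory.GAIN for c in observed):
        return Trailing3Summary.ALL_GAIN
    net_cat = categorize_weight_change(net_change)
    if net_cat == WeightCategory.GAIN:
        return Trailing3Summary.MIXED_GAIN
    if net_cat == WeightCategory.LOSS:
        return Trailing3Summary.MIXED_LOSS
    return Trailing3Summary.FLAT


def cum_pct_band(cum_pct_change: Optional[float]) -> CumPctBand:
    """Band of cumulative percent change used by weight-message criteria.

    Partition: (-inf,-10], (-10,-5], (-5,-2], (-2,0], (0,inf); UNKNOWN
    when the change is absent.
    """
    if cum_pct_change is None:
        return CumPctBand.UNKNOWN
    if cum_pct_change <= -10:
        return CumPctBand.LE_NEG10
    if cum_pct_change <= -5:
        return CumPctBand.NEG10_NEG5
    if cum_pct_change <= -2:
        return CumPctBand.NEG5_NEG2
    if cum_pct_change <= 0:
        return CumPctBand.NEG2_0
    return CumPctBand.POS


def _weekly_weight(records: Sequence[DailyRecord], window: WeekWindow,
                   reduction: str) -> Optional[float]:
    """Reduce the window's weigh-ins to one value (last by default)."""
    weights = [(r.date, r.weight) for r in records
               if window.contains(r.date) and r.weight is not None]
    if not weights:
        return None
    if reduction == "mean":
        return sum(w for _, w in weights) / len(weights)
    return max(weights)[1]  # records are date-sorted; max date = last weigh-in


def aggregate_week(records: Sequence[DailyRecord], window: WeekWindow,
                   profile: ParticipantProfile,
                   prior_weeks: Sequence[WeeklyVariables] = (),
                   weight_reduction: Literal["last", "mean"] = "last",
                   ) -> WeeklyVariables:
    """Compute the weekly tailoring variables for one program week.

    ``records`` must be validated (sorted, de-duplicated); ``prior_weeks``
    must hold the variables of weeks 1..k-1 in order (data gaps are fine,
    index gaps are not).  The weekly weight is the last weigh-in of the
    window (``weight_reduction="mean"`` switches to the window mean);
    weight change subtracts the previous window's weekly weight and is
    absent if either side is missing.  Days below the calorie range are
    treated as likely underreporting, so ``monitoring_days`` counts only
    days within or above the range.  The trailing trend covers program
    weeks k-4..k-2 — the three weeks prior to last week — skipping absent
    entries.
    """
    k = window.week_index
    offset = (window.start_date - profile.program_start).days
    if offset != 7 * (k - 1):
        raise ValidationError(
            f"window for week {k} must start {7 * (k - 1)} days after "
            f"program start, got offset {offset}")
    if [w.week_index for w in prior_weeks] != list(range(1, k)):
        raise ValidationError(
            f"prior_weeks must cover week indices 1..{k - 1} contiguously")

    in_window = [r for r in records if window.contains(r.date)]

    this_weight = _weekly_weight(records, window, weight_reduction)
    # Week 1 has no previous program week, so its change is always absent.
    prev_window = (WeekWindow.for_week(profile.program_start, k - 1)
                   if k > 1 else None)
    prev_weight = (_weekly_weight(records, prev_window, weight_reduction)
                   if prev_window else None)
    weight_change = (this_weight - prev_weight
                     if this_weight is not None and prev_weight is not None
                     else None)

    low, high = compute_calorie_range(profile.calorie_goal)
    cal_days = [r.calories for r in in_window if r.calories is not None]
    days_in = sum(1 for c in cal_days if low <= c <= high)
    days_above = sum(1 for c in cal_days if c > high)
    days_below = sum(1 for c in cal_days if c < low)

    trailing = [w for w in prior_weeks if k - 4 <= w.week_index <= k - 2]
    trailing_changes = [w.weight_change for w in trailing
                        if w.weight_change is not None]
    trailing_net = sum(trailing_changes) if trailing_changes else None

    return WeeklyVariables(
        week_index=k,
        weight_change=weight_change,
        weight_category=categorize_weight_change(weight_change),
        cum_pct_change=(100.0 * (this_weight - profile.baseline_weight)
                        / profile.baseline_weight
                        if this_weight is not None else None),
        days_self_weighed=sum(1 for r in in_window if r.weight is not None),
        mvpa_minutes=sum(r.mvpa_minutes for r in in_window
                         if r.mvpa_minutes is not None),
        activity_tracking_days=sum(1 for r in in_window
                                   if r.mvpa_minutes is not None
                                   and r.mvpa_minutes > 0),
        avg_calorie_intake=(sum(cal_days) / len(cal_days) if cal_days else None),
        days_in_range=days_in,
        days_above_range=days_above,
        days_below_range=days_below,
        monitoring_days=days_in + days_above,
        app_used=any(r.app_opened for r in in_window),
        trailing3_net_change=trailing_net,
        trailing3_categories=[w.weight_category for w in trailing],
    )


def detect_milestones(cum_pct_change: float,
                      history: ParticipantHistory) -> set[Milestone]:
    """First-time 5% / 10% weight-loss milestone events for this week.

    A milestone fires when cumulative percent change reaches its threshold
    (``<= -5`` / ``<= -10``, exact comparison on the unrounded value) and
    has not fired before for this participant; one week can fire both.
    The caller records fired events into the history exactly once.
    """
    return {m for m, thresh in MILESTONE_THRESHOLDS.items()
            if cum_pct_change <= thresh and m not in history.milestones_reached}


def weekly_variables_table(weeks: Sequence[WeeklyVariables],
                           participant_id: str) -> pd.DataFrame:
    """Audit table: one row per participant-week with every variable field."""
    rows = []
    for w in weeks:
        row = w.model_dump()
        row["weight_category"] = w.weight_category.value
        row["trailing3_categories"] = "|".join(
            c.value for c in w.trailing3_categories)
        row["participant_id"] = participant_id
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df[["participant_id"] + [c for c in df.columns
                                      if c != "participant_id"]]
    return df
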