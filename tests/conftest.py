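"""Shared fixtures: the default bank, a minimal bank builder, the naive
weekly re-count oracle, and random-week generators.

The oracle deliberately re-implements the weekly aggregation as literal
single-pass loops over raw rows, independent of the package's own code
path, so equivalence tests are meaningful.
"""

from __future__ import annotations

import datetime as dt
from typing import Any, Optional, Sequence

import numpy as np
import pytest

from weeklycoach.domain_model import (
    DailyRecord,
    Intent,
    ParticipantProfile,
)
from weeklycoach.message_bank import MessageBank, load_bank
from weeklycoach.weekly_aggregation import WeekWindow

PROGRAM_START = dt.date(2026, 1, 5)


@pytest.fixture(scope="session")
def default_bank() -> MessageBank:
    return load_bank()


@pytest.fixture
def profile() -> ParticipantProfile:
    return ParticipantProfile(
        participant_id="p1", baseline_weight=200.0, calorie_goal=1800.0,
        activity_goal=150.0, intent=Intent.LOSE, rescue_mode=False,
        program_start=PROGRAM_START)


# ---------------------------------------------------------------------------
# Minimal-bank builder
# ---------------------------------------------------------------------------

_DOMAINS = ["SELF_WEIGHING", "DIETARY_MONITORING", "CALORIE_INTAKE",
            "PHYSICAL_ACTIVITY", "APP_USE"]


def bank_dict(**overrides: Any) -> dict:
    """A minimal valid bank as a plain dict, for mutation in tests."""
    data: dict[str, Any] = {
        "bank_schema": 1,
        "weight_messages": [
            {"id": "w1", "criteria": [], "text": "Weight note one."},
            {"id": "w2", "criteria": [], "text": "Weight note two."},
        ],
        "themes": [
            {"id": "alpha", "label": "Alpha", "weights":
                {"DECLINING": 0.5, "FLAT": 0.5, "IMPROVING": 0.5}},
            {"id": "beta", "label": "Beta", "weights":
                {"DECLINING": 0.5, "FLAT": 0.5, "IMPROVING": 0.5}},
        ],
        "parent_messages": [
            {"id": "pa", "theme_id": "alpha", "domain": "APP_USE",
             "criteria": [], "text": "Alpha fallback.", "is_fallback": True},
            {"id": "pb", "theme_id": "beta", "domain": "APP_USE",
             "criteria": [], "text": "Beta fallback.", "is_fallback": True},
        ],
        "targeted_messages": [
            {"id": f"t-{dom}-{typ}", "domain": dom, "type": typ,
             "text": f"{typ.title()} for {dom}."}
            for dom in _DOMAINS for typ in ("REINFORCEMENT", "STRATEGY")
        ],
        "milestone_texts": {
            "FIVE_PCT": "Five percent milestone reached.",
            "TEN_PCT": "Ten percent milestone reached.",
        },
        "no_weigh_reminder": "Please weigh in regularly.",
        "rescue_checkin_texts": ["Just checking in, no numbers today."],
    }
    data.update(overrides)
    return data


def make_bank(**overrides: Any) -> MessageBank:
    return MessageBank.model_validate(bank_dict(**overrides))


@pytest.fixture
def minimal_bank() -> MessageBank:
    return make_bank()


# ---------------------------------------------------------------------------
# Random week generation
# ---------------------------------------------------------------------------

def random_day(rng: np.random.Generator, date: dt.date) -> DailyRecord:
    """One day with independently missing observations, edge values included."""
    weight = float(rng.uniform(150, 250)) if rng.random() < 0.7 else None
    calories = None
    if rng.random() < 0.7:
        # Straddle the 1500-1800 default range, boundaries included.
        calories = float(rng.choice(
            [rng.uniform(800, 2600), 1500.0, 1800.0, 1499.9, 1800.1]))
    mvpa = None
    if rng.random() < 0.7:
        mvpa = 0.0 if rng.random() < 0.2 else float(rng.uniform(1, 90))
    return DailyRecord(date=date, weight=weight, calories=calories,
                       mvpa_minutes=mvpa,
                       app_opened=bool(rng.random() < 0.4))


def random_history_records(rng: np.random.Generator, n_weeks: int,
                           program_start: dt.date = PROGRAM_START,
                           ) -> list[DailyRecord]:
    """Random daily records spanning ``n_weeks`` program weeks."""
    return [random_day(rng, program_start + dt.timedelta(days=d))
            for d in range(7 * n_weeks)]


# ---------------------------------------------------------------------------
# Naive re-count oracle
# ---------------------------------------------------------------------------

def _last_weigh_in(records: Sequence[DailyRecord], start: dt.date,
                   end: dt.date) -> Optional[float]:
    best: Optional[tuple[dt.date, float]] = None
    for r in records:
        if start <= r.date <= end and r.weight is not None:
            if best is None or r.date > best[0]:
                best = (r.date, r.weight)
    return None if best is None else best[1]


def naive_week_recount(records: Sequence[DailyRecord], window: WeekWindow,
                       profile: ParticipantProfile) -> dict[str, Any]:
    """Literal re-count of every weekly variable straight from raw rows.

    Written independently of the aggregation module: explicit loops, no
    shared helpers.  Trailing-trend fields are recounted from the raw rows
    of program weeks k-4..k-2 as week-over-week last-weigh-in differences.
    """
    k = window.week_index
    start, end = window.start_date, window.end_date

    this_w = _last_weigh_in(records, start, end)
    prev_w = _last_weigh_in(records, start - dt.timedelta(days=7),
                            start - dt.timedelta(days=1)) if k > 1 else None
    change = this_w - prev_w if this_w is not None and prev_w is not None else None
    if change is None:
        category = "UNKNOWN"
    elif change < -0.4:
        category = "LOSS"
    elif change > 0.4:
        category = "GAIN"
    else:
        category = "MAINTENANCE"

    low = profile.calorie_goal - 300.0
    high = profile.calorie_goal
    days_weighed = n_in = n_above = n_below = n_logged = tracking = 0
    mvpa_total = 0.0
    cal_total = 0.0
    app = False
    for r in records:
        if not (start <= r.date <= end):
            continue
        if r.weight is not None:
            days_weighed += 1
        if r.calories is not None:
            n_logged += 1
            cal_total += r.calories
            if low <= r.calories <= high:
                n_in += 1
            elif r.calories > high:
                n_above += 1
            else:
                n_below += 1
        if r.mvpa_minutes is not None:
            mvpa_total += r.mvpa_minutes
            if r.mvpa_minutes > 0:
                tracking += 1
        if r.app_opened:
            app = True

    trailing_changes = []
    trailing_categories = []
    for j in range(max(1, k - 4), k - 1):
        j_start = profile.program_start + dt.timedelta(days=7 * (j - 1))
        j_end = j_start + dt.timedelta(days=6)
        wj = _last_weigh_in(records, j_start, j_end)
        wjp = (_last_weigh_in(records, j_start - dt.timedelta(days=7),
                              j_start - dt.timedelta(days=1))
               if j > 1 else None)
        cj = wj - wjp if wj is not None and wjp is not None else None
        if cj is None:
            trailing_categories.append("UNKNOWN")
        else:
            trailing_changes.append(cj)
            trailing_categories.append(
                "LOSS" if cj < -0.4 else "GAIN" if cj > 0.4 else "MAINTENANCE")

    return {
        "week_index": k,
        "weight_change": change,
        "weight_category": category,
        "cum_pct_change": (100.0 * (this_w - profile.baseline_weight)
                           / profile.baseline_weight
                           if this_w is not None else None),
        "days_self_weighed": days_weighed,
        "mvpa_minutes": mvpa_total,
        "activity_tracking_days": tracking,
        "avg_calorie_intake": cal_total / n_logged if n_logged else None,
        "days_in_range": n_in,
        "days_above_range": n_above,
        "days_below_range": n_below,
        "monitoring_days": n_in + n_above,
        "app_used": app,
        "trailing3_net_change": (sum(trailing_changes)
                                 if trailing_changes else None),
        "trailing3_categories": trailing_categories,
    }
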