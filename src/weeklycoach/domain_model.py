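"""Shared domain types for the weekly coaching-message engine.

The engine turns daily self-monitoring observations (morning weight, logged
calorie intake, activity-tracker minutes, app opens) into one tailored
coaching message per participant-week.  Every other module speaks in the
types defined here:

* :class:`DailyRecord` — one calendar day of raw observations.
* :class:`ParticipantProfile` — goals and flags that tailor the message.
* :class:`WeeklyVariables` — the eight weekly tailoring variables plus
  derived categories, computed by :mod:`weeklycoach.weekly_aggregation`.
* :class:`ParticipantHistory` — the per-participant memory that the
  anti-repetition and milestone rules need.
* :class:`CoachingMessage` — the assembled weekly output with its audit
  trail.

Units are pounds (lbs) and kilocalories (kcal) throughout; no metric
conversion layer is provided (conversion belongs upstream).
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "DailyRecord",
    "ParticipantProfile",
    "WeeklyVariables",
    "ParticipantHistory",
    "CoachingMessage",
    "WeightFeedback",
    "BehavioralFeedback",
    "SelectionAudit",
    "StageAudit",
    "Intent",
    "WeightCategory",
    "Trailing3Summary",
    "CumPctBand",
    "Milestone",
    "Domain",
    "MessageKind",
    "ValidationError",
    "validate_daily_records",
    "read_daily_records_csv",
    "write_daily_records_csv",
    "load_profile",
]


class ValidationError(Exception):
    """Raised when input data violates a domain invariant.

    Deliberately not a ValueError: pydantic would otherwise swallow it
    inside model validation and re-wrap it, losing the domain message.
    """


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Intent(str, enum.Enum):
    """Whether the participant currently reports trying to lose or maintain."""

    LOSE = "LOSE"
    MAINTAIN = "MAINTAIN"


class WeightCategory(str, enum.Enum):
    """Past-week weight-change category.

    Loss is a drop of more than 0.4 lbs, gain a rise of more than 0.4 lbs,
    maintenance the inclusive band in between; UNKNOWN means the change
    could not be computed (a weigh-in was missing on either side).
    """

    LOSS = "LOSS"
    MAINTENANCE = "MAINTENANCE"
    GAIN = "GAIN"
    UNKNOWN = "UNKNOWN"


class Trailing3Summary(str, enum.Enum):
    """Discretized summary of the three program weeks prior to last week.

    ALL_LOSS / ALL_GAIN: every observed weekly category agreed.
    MIXED_LOSS / MIXED_GAIN: categories disagreed; the sign names the net
    change over the window (net below -0.4 lbs / above +0.4 lbs).
    FLAT: net change within the maintenance band.
    UNKNOWN: no weekly change observable in the window.
    """

    ALL_LOSS = "ALL_LOSS"
    ALL_GAIN = "ALL_GAIN"
    MIXED_LOSS = "MIXED_LOSS"
    MIXED_GAIN = "MIXED_GAIN"
    FLAT = "FLAT"
    UNKNOWN = "UNKNOWN"


class CumPctBand(str, enum.Enum):
    """Cumulative percent-weight-change band used in weight-message criteria.

    Bands partition the line at -10, -5, -2 and 0 percent:
    LE_NEG10 = (-inf, -10], NEG10_NEG5 = (-10, -5], NEG5_NEG2 = (-5, -2],
    NEG2_0 = (-2, 0], POS = (0, inf).  UNKNOWN when no weigh-in this week.
    """

    LE_NEG10 = "LE_NEG10"
    NEG10_NEG5 = "NEG10_NEG5"
    NEG5_NEG2 = "NEG5_NEG2"
    NEG2_0 = "NEG2_0"
    POS = "POS"
    UNKNOWN = "UNKNOWN"


class Milestone(str, enum.Enum):
    """First-time cumulative weight-loss milestones."""

    FIVE_PCT = "FIVE_PCT"
    TEN_PCT = "TEN_PCT"


class Domain(str, enum.Enum):
    """Behavioral prescription addressed by a behavioral-feedback message."""

    SELF_WEIGHING = "SELF_WEIGHING"
    DIETARY_MONITORING = "DIETARY_MONITORING"
    CALORIE_INTAKE = "CALORIE_INTAKE"
    PHYSICAL_ACTIVITY = "PHYSICAL_ACTIVITY"
    APP_USE = "APP_USE"


class MessageKind(str, enum.Enum):
    FULL = "FULL"
    RESCUE_CHECKIN = "RESCUE_CHECKIN"


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

class DailyRecord(BaseModel):
    """One calendar day of self-monitoring observations for one participant.

    Absent ``weight`` means the participant did not self-weigh that day;
    absent ``calories`` means no dietary records; absent ``mvpa_minutes``
    means the tracker recorded no activity (not worn or idle).  Upstream
    systems with intraday weigh-ins must pre-reduce to one value per day
    (first-of-day by convention).
    """

    model_config = {"frozen": True}

    date: dt.date
    weight: Optional[float] = Field(default=None, gt=50, lt=1000,
                                    description="Body mass, lbs")
    calories: Optional[float] = Field(default=None, ge=0, le=20000,
                                      description="Total logged intake, kcal")
    mvpa_minutes: Optional[float] = Field(default=None, ge=0,
                                          description="Active-zone minutes")
    app_opened: bool = False


class ParticipantProfile(BaseModel):
    """Program goals and flags for one participant.

    ``calorie_goal`` is the upper bound of the target calorie range; the
    range spans 300 kcal below the goal up to the goal, so the goal must be
    at least 300 kcal.  ``baseline_weight`` is the weight measured in
    program week 1, the reference for cumulative percent change.
    """

    model_config = {"frozen": True}

    participant_id: str
    baseline_weight: float = Field(gt=0)
    calorie_goal: float = Field(ge=300)
    activity_goal: float = Field(ge=0, description="Weekly MVPA-minutes target")
    intent: Intent = Intent.LOSE
    rescue_mode: bool = False
    program_start: dt.date


class WeeklyVariables(BaseModel):
    """The weekly tailoring variables for one participant-week.

    The eight core variables are: past-week weight change, cumulative
    percent weight change from baseline, days self-weighed, weekly MVPA
    minutes, activity tracking days, average calorie intake, days
    within/above/below the target calorie range, and app use.  Derived
    fields (category, bands, trailing trend, monitoring days) support
    message criteria.  ``monitoring_days`` counts days within or above the
    calorie range; below-range days are treated as likely underreporting
    and do not count toward dietary self-monitoring adherence.
    """

    model_config = {"frozen": True}

    week_index: int = Field(ge=1)
    weight_change: Optional[float] = None
    weight_category: WeightCategory = WeightCategory.UNKNOWN
    cum_pct_change: Optional[float] = None
    days_self_weighed: int = Field(ge=0, le=7)
    mvpa_minutes: float = Field(ge=0)
    activity_tracking_days: int = Field(ge=0, le=7)
    avg_calorie_intake: Optional[float] = None
    days_in_range: int = Field(ge=0, le=7)
    days_above_range: int = Field(ge=0, le=7)
    days_below_range: int = Field(ge=0, le=7)
    monitoring_days: int = Field(ge=0, le=7)
    app_used: bool = False
    trailing3_net_change: Optional[float] = None
    trailing3_categories: list[WeightCategory] = Field(default_factory=list,
                                                       max_length=3)

    @model_validator(mode="after")
    def _check_consistency(self) -> "WeeklyVariables":
        if self.days_in_range + self.days_above_range + self.days_below_range > 7:
            raise ValueError("calorie-day counts exceed 7")
        if self.monitoring_days != self.days_in_range + self.days_above_range:
            raise ValueError("monitoring_days must equal days_in + days_above")
        if (self.weight_category == WeightCategory.UNKNOWN) != (
                self.weight_change is None):
            raise ValueError("weight_category is UNKNOWN iff weight_change absent")
        return self


# ---------------------------------------------------------------------------
# Output and history
# ---------------------------------------------------------------------------

class StageAudit(BaseModel):
    """Audit record of one selection stage (weight / theme / parent / targeted)."""

    stage: str
    candidates: list[str] = Field(default_factory=list)
    excluded: dict[str, str] = Field(default_factory=dict)  # id -> reason
    random_draw: Optional[float] = None
    chosen: Optional[str] = None
    fallback: bool = False
    notes: str = ""


class SelectionAudit(BaseModel):
    """Complete machine-readable trail of one week's selection decisions."""

    rng_seed: int
    stages: list[StageAudit] = Field(default_factory=list)

    def stage(self, name: str) -> StageAudit:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)


class WeightFeedback(BaseModel):
    """Weight component: either a bank message or the self-weigh reminder."""

    kind: str  # "message" | "reminder"
    message_id: Optional[str] = None
    milestone_texts: list[str] = Field(default_factory=list)
    text: str


class BehavioralFeedback(BaseModel):
    """Behavioral component: theme -> parent subcomponent -> optional targeted."""

    theme_id: str
    parent_id: str
    domain: Domain
    targeted_id: Optional[str] = None
    text: str


class CoachingMessage(BaseModel):
    """The assembled weekly output.

    A FULL message carries the summary box, a weight component and a
    behavioral component; a RESCUE_CHECKIN carries only neutral check-in
    text that references no participant data.
    """

    participant_id: str
    week_index: int = Field(ge=1)
    kind: MessageKind
    summary_box: Optional[str] = None
    weight_component: Optional[WeightFeedback] = None
    behavioral_component: Optional[BehavioralFeedback] = None
    checkin_text: Optional[str] = None
    audit: SelectionAudit

    @model_validator(mode="after")
    def _check_kind(self) -> "CoachingMessage":
        if self.kind == MessageKind.RESCUE_CHECKIN:
            if (self.summary_box is not None or self.weight_component is not None
                    or self.behavioral_component is not None):
                raise ValueError("rescue check-in must carry no data components")
            if not self.checkin_text:
                raise ValueError("rescue check-in requires checkin_text")
        else:
            if self.summary_box is None or self.behavioral_component is None:
                raise ValueError("FULL message requires summary box and "
                                 "behavioral component")
        return self


class ParticipantHistory(BaseModel):
    """Per-participant memory for anti-repetition and milestone rules.

    ``sent_weight_message_ids`` maps a weight-criteria signature key to the
    ordered list of message ids already sent at that signature (append
    order = send order, so the least recently sent id is the earliest
    occurrence).  Logs are append-only and ordered by week index.
    """

    participant_id: str
    sent_weight_message_ids: dict[str, list[str]] = Field(default_factory=dict)
    last_theme: Optional[str] = None
    last_parent_domain: Optional[Domain] = None
    milestones_reached: set[Milestone] = Field(default_factory=set)
    rescue_weeks_seen: int = 0
    weekly_variables_log: list[WeeklyVariables] = Field(default_factory=list)
    messages_log: list[CoachingMessage] = Field(default_factory=list)

    def record_weight_send(self, signature: str, message_id: str) -> None:
        self.sent_weight_message_ids.setdefault(signature, []).append(message_id)

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ParticipantHistory":
        return cls.model_validate_json(text)


# ---------------------------------------------------------------------------
# Validation and I/O
# ---------------------------------------------------------------------------

def validate_daily_records(records: list[DailyRecord]) -> list[DailyRecord]:
    """Return de-duplicated, date-sorted records; reject inconsistent input.

    Identical duplicate days collapse to one record.  Two records for the
    same date with conflicting values are a validation error naming the
    date — values are never repaired or merged.  Field-level range checks
    happen at :class:`DailyRecord` construction.
    """
    by_date: dict[dt.date, DailyRecord] = {}
    for rec in records:
        prev = by_date.get(rec.date)
        if prev is None:
            by_date[rec.date] = rec
        elif prev != rec:
            raise ValidationError(
                f"conflicting duplicate records for {rec.date.isoformat()}")
    return [by_date[d] for d in sorted(by_date)]


_CSV_HEADER = ["date", "weight_lbs", "calories_kcal", "mvpa_minutes", "app_opened"]


def _parse_cell(value: str) -> Optional[float]:
    value = value.strip()
    return float(value) if value else None


def read_daily_records_csv(path: str | Path) -> list[DailyRecord]:
    """Read daily records from delimited text.

    Expected header ``date,weight_lbs,calories_kcal,mvpa_minutes,app_opened``
    with ISO-8601 dates; an empty cell means the observation is absent.
    Records are validated and de-duplicated on the way in.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _CSV_HEADER:
            raise ValidationError(
                f"expected header {','.join(_CSV_HEADER)!r}, "
                f"got {reader.fieldnames!r} in {path}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(DailyRecord(
                    date=dt.date.fromisoformat(row["date"].strip()),
                    weight=_parse_cell(row["weight_lbs"]),
                    calories=_parse_cell(row["calories_kcal"]),
                    mvpa_minutes=_parse_cell(row["mvpa_minutes"]),
                    app_opened=row["app_opened"].strip().lower()
                    in ("1", "true", "yes"),
                ))
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"row {i} of {path}: {exc}") from exc
    return validate_daily_records(records)


def write_daily_records_csv(records: list[DailyRecord], path: str | Path) -> None:
    """Write daily records as delimited text (inverse of the reader)."""

    def cell(v: Optional[float]) -> str:
        return "" if v is None else format(v, "g")

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for rec in records:
            writer.writerow([
                rec.date.isoformat(), cell(rec.weight), cell(rec.calories),
                cell(rec.mvpa_minutes), "true" if rec.app_opened else "false",
            ])


def load_profile(path: str | Path) -> ParticipantProfile:
    """Load a participant profile from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    try:
        return ParticipantProfile.model_validate(data)
    except Exception as exc:
        raise ValidationError(f"invalid profile {path}: {exc}") from exc
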