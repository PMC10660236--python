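"""Synthetic daily-record trajectories, canned scenarios, and the trial runner.

The simulator emulates the data streams a behavioral weight-loss program
collects: daily morning weigh-ins from a connected scale, logged calorie
intake, tracker activity minutes, and app opens.  Body weight follows a
linear weekly drift plus IID Gaussian day-to-day noise — deliberately the
simplest process that exercises every weight category, trend, and
milestone path; it is not a physiological model (no autocorrelation, no
plateaus unless scripted).  Each observation stream is thinned by an
independent Bernoulli adherence coin.

Canned scenarios are deterministic fixtures with a named property
(a steady loser, a plateau, a regainer matching the mixed-gains weight
signature, an intake underreporter, ...).  ``run_trial`` drives the full
engine over a cohort, threading history week by week, and produces
message logs, JSONL audits, and a cohort report.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .domain_model import (
    CoachingMessage,
    DailyRecord,
    Intent,
    MessageKind,
    ParticipantHistory,
    ParticipantProfile,
)
from .message_bank import MessageBank
from .renderer import delivery_manifest, render_message
from .selection_engine import compose_week
from .weekly_aggregation import WeekWindow, weekly_variables_table

__all__ = [
    "TrajectoryParams",
    "simulate_participant",
    "make_scenario",
    "SCENARIO_NAMES",
    "TrialResult",
    "run_trial",
]

logger = logging.getLogger(__name__)

#: Fixed anchor date for synthetic programs (a Monday; arbitrary but stable).
DEFAULT_PROGRAM_START = dt.date(2026, 1, 5)


class TrajectoryParams(BaseModel):
    """Parameters of one synthetic participant trajectory.

    Weight on program day ``d`` (1-based) is
    ``start_weight + weekly_drift * d / 7 + Normal(0, day_noise_sd)``,
    observed only on days where the weigh-in coin (``p_weigh``) lands.
    Calorie and activity streams are thinned the same way by ``p_log`` and
    ``p_wear``; ``p_app_open`` is the weekly probability of at least one
    app open.  All randomness comes from ``seed``.
    """

    model_config = {"frozen": True}

    n_weeks: int = Field(ge=1, default=12)
    start_weight: float = Field(gt=50, lt=1000, default=220.0)
    weekly_drift: float = -0.5
    day_noise_sd: float = Field(ge=0, default=1.0)
    p_weigh: float = Field(ge=0, le=1, default=0.75)
    p_log: float = Field(ge=0, le=1, default=0.7)
    p_wear: float = Field(ge=0, le=1, default=0.8)
    calorie_mean: float = Field(ge=0, default=1700.0)
    calorie_sd: float = Field(ge=0, default=300.0)
    mvpa_mean: float = Field(default=25.0, description="Minutes per worn day")
    mvpa_sd: float = Field(ge=0, default=15.0)
    p_app_open: float = Field(ge=0, le=1, default=0.6)
    seed: int = 0
    program_start: dt.date = DEFAULT_PROGRAM_START


def simulate_participant(params: TrajectoryParams) -> list[DailyRecord]:
    """Simulate one participant's daily records, deterministically in the seed."""
    rng = np.random.default_rng(params.seed)
    # Weekly app-open schedule drawn up front so day loops stay simple.
    app_days: set[int] = set()
    for week in range(params.n_weeks):
        if rng.random() < params.p_app_open:
            app_days.add(7 * week + int(rng.integers(7)) + 1)

    records = []
    for d in range(1, 7 * params.n_weeks + 1):
        weight = calories = mvpa = None
        if rng.random() < params.p_weigh:
            weight = (params.start_weight + params.weekly_drift * d / 7
                      + rng.normal(0.0, params.day_noise_sd))
        if rng.random() < params.p_log:
            calories = max(0.0, rng.normal(params.calorie_mean, params.calorie_sd))
        if rng.random() < params.p_wear:
            mvpa = max(0.0, rng.normal(params.mvpa_mean, params.mvpa_sd))
        records.append(DailyRecord(
            date=params.program_start + dt.timedelta(days=d - 1),
            weight=weight, calories=calories, mvpa_minutes=mvpa,
            app_opened=d in app_days))
    return records


def _default_profile(participant_id: str, baseline_weight: float,
                     rescue: bool = False) -> ParticipantProfile:
    return ParticipantProfile(
        participant_id=participant_id, baseline_weight=baseline_weight,
        calorie_goal=1800.0, activity_goal=150.0, intent=Intent.LOSE,
        rescue_mode=rescue, program_start=DEFAULT_PROGRAM_START)


def _scripted_weekly_weights(weekly_weights: Sequence[float],
                             calories: float = 1650.0,
                             mvpa: float = 20.0) -> list[DailyRecord]:
    """Records with exactly one weigh-in per week (on the week's last day)."""
    records = []
    for week, weight in enumerate(weekly_weights, start=1):
        for day in range(7 * (week - 1) + 1, 7 * week + 1):
            last_day = day == 7 * week
            records.append(DailyRecord(
                date=DEFAULT_PROGRAM_START + dt.timedelta(days=day - 1),
                weight=weight if last_day else None,
                calories=calories, mvpa_minutes=mvpa,
                app_opened=last_day))
    return records


SCENARIO_NAMES = ("steady_loser", "plateau", "regainer", "underreporter",
                  "no_weigh_week", "milestone_cross", "perfect_adherence",
                  "rescue")


def make_scenario(name: str, seed: Optional[int] = None,
                  ) -> tuple[list[DailyRecord], ParticipantProfile]:
    """Deterministic fixture with a named property.

    * ``steady_loser`` — consistent moderate loss, good adherence.
    * ``plateau`` — zero drift: maintenance weeks.
    * ``regainer`` — scripted weigh-ins reproducing the mixed-gains weight
      signature at week 6 (past-week gain, net trailing gain, overall gain).
    * ``underreporter`` — every logged day far below the calorie range, so
      monitoring days stay near zero despite complete logs.
    * ``no_weigh_week`` — week 3 has no weigh-ins at all.
    * ``milestone_cross`` — noise-free 1 lb/week loss from 200 lbs; the 5%
      milestone falls exactly at week 10.
    * ``perfect_adherence`` — every stream observed every day.
    * ``rescue`` — a participant with rescue mode switched on.

    Scenarios carry fixed per-name seeds so the fixtures are stable; pass
    ``seed`` to get an alternative draw of the stochastic ones.
    """
    base = dict(program_start=DEFAULT_PROGRAM_START)
    if name == "steady_loser":
        params = TrajectoryParams(n_weeks=12, start_weight=200.0,
                                  weekly_drift=-1.0, day_noise_sd=0.5,
                                  p_weigh=0.9, p_log=0.85, p_wear=0.9,
                                  calorie_mean=1650.0, calorie_sd=120.0,
                                  seed=seed if seed is not None else 101, **base)
        return simulate_participant(params), _default_profile(name, 200.0)
    if name == "plateau":
        params = TrajectoryParams(n_weeks=12, start_weight=210.0,
                                  weekly_drift=0.0, day_noise_sd=0.3,
                                  p_weigh=0.9, p_log=0.8, p_wear=0.85,
                                  seed=seed if seed is not None else 102, **base)
        return simulate_participant(params), _default_profile(name, 210.0)
    if name == "regainer":
        weekly = [200.0, 201.0, 200.2, 201.5, 201.0, 202.0, 201.4, 202.1]
        return _scripted_weekly_weights(weekly), _default_profile(name, 200.0)
    if name == "underreporter":
        params = TrajectoryParams(n_weeks=8, start_weight=230.0,
                                  weekly_drift=-0.3, day_noise_sd=0.5,
                                  p_weigh=0.8, p_log=1.0, p_wear=0.7,
                                  calorie_mean=900.0, calorie_sd=50.0,
                                  seed=seed if seed is not None else 104, **base)
        return simulate_participant(params), _default_profile(name, 230.0)
    if name == "no_weigh_week":
        records, profile = make_scenario("steady_loser", seed=seed)
        window = WeekWindow.for_week(DEFAULT_PROGRAM_START, 3)
        records = [r.model_copy(update={"weight": None})
                   if window.contains(r.date) else r for r in records]
        return records, profile.model_copy(update={"participant_id": name})
    if name == "milestone_cross":
        params = TrajectoryParams(n_weeks=12, start_weight=200.0,
                                  weekly_drift=-1.0, day_noise_sd=0.0,
                                  p_weigh=1.0, p_log=1.0, p_wear=1.0,
                                  calorie_mean=1650.0, calorie_sd=0.0,
                                  mvpa_mean=25.0, mvpa_sd=0.0, p_app_open=1.0,
                                  seed=seed if seed is not None else 105, **base)
        return simulate_participant(params), _default_profile(name, 200.0)
    if name == "perfect_adherence":
        params = TrajectoryParams(n_weeks=12, start_weight=195.0,
                                  weekly_drift=-0.8, day_noise_sd=0.4,
                                  p_weigh=1.0, p_log=1.0, p_wear=1.0,
                                  p_app_open=1.0,
                                  seed=seed if seed is not None else 106, **base)
        return simulate_participant(params), _default_profile(name, 195.0)
    if name == "rescue":
        records, _ = make_scenario("plateau", seed=seed)
        return records, _default_profile(name, 210.0, rescue=True)
    raise ValueError(f"unknown scenario {name!r}; valid names: "
                     f"{', '.join(SCENARIO_NAMES)}")


# ---------------------------------------------------------------------------
# Trial runner
# ---------------------------------------------------------------------------

class TrialResult(BaseModel):
    """Everything a simulated trial produces, before any file is written."""

    global_seed: int
    n_weeks: int
    messages: dict[str, list[CoachingMessage]]
    histories: dict[str, ParticipantHistory]
    errors: list[str] = Field(default_factory=list)
    report: dict = Field(default_factory=dict)


def _cohort_report(messages: dict[str, list[CoachingMessage]],
                   histories: dict[str, ParticipantHistory]) -> dict:
    theme_usage: dict[str, int] = {}
    theme_transitions: dict[str, int] = {}
    domain_transitions: dict[str, int] = {}
    milestone_events: dict[str, list[str]] = {}
    fallback_invocations = 0
    domain_repeats_permitted = 0
    for pid, msgs in messages.items():
        prev_theme = prev_domain = None
        for m in msgs:
            if m.kind != MessageKind.FULL:
                continue
            b = m.behavioral_component
            assert b is not None
            theme_usage[b.theme_id] = theme_usage.get(b.theme_id, 0) + 1
            if prev_theme is not None:
                key = f"{prev_theme}->{b.theme_id}"
                theme_transitions[key] = theme_transitions.get(key, 0) + 1
            if prev_domain is not None:
                key = f"{prev_domain.value}->{b.domain.value}"
                domain_transitions[key] = domain_transitions.get(key, 0) + 1
            prev_theme, prev_domain = b.theme_id, b.domain
            for s in m.audit.stages:
                if s.fallback:
                    fallback_invocations += 1
                if "domain repeat permitted" in s.notes:
                    domain_repeats_permitted += 1
            if (m.weight_component is not None
                    and m.weight_component.milestone_texts):
                milestone_events.setdefault(pid, [])
        milestone_events[pid] = sorted(
            e.value for e in histories[pid].milestones_reached)
    return {
        "theme_usage": dict(sorted(theme_usage.items())),
        "theme_transitions": dict(sorted(theme_transitions.items())),
        "domain_transitions": dict(sorted(domain_transitions.items())),
        "milestones": milestone_events,
        "fallback_invocations": fallback_invocations,
        "domain_repeats_permitted": domain_repeats_permitted,
    }


def run_trial(cohort: Sequence[tuple[ParticipantProfile, list[DailyRecord]]],
              bank: MessageBank, global_seed: int,
              n_weeks: Optional[int] = None,
              outdir: Optional[str | Path] = None) -> TrialResult:
    """Run the weekly engine over a cohort, threading history per participant.

    ``n_weeks`` defaults to the span of each participant's records.  Stage
    errors are collected per participant-week and the run continues.  With
    ``outdir`` set, per-participant message logs, JSONL audits, a weekly
    variables table, delivery manifests and the cohort report are written
    there.  Deterministic in ``global_seed``.
    """
    messages: dict[str, list[CoachingMessage]] = {}
    histories: dict[str, ParticipantHistory] = {}
    errors: list[str] = []
    for profile, records in cohort:
        pid = profile.participant_id
        weeks = n_weeks
        if weeks is None:
            span = (max(r.date for r in records) - profile.program_start).days + 1
            weeks = span // 7
        history = ParticipantHistory(participant_id=pid)
        histories[pid] = history
        messages[pid] = []
        for k in range(1, weeks + 1):
            window = WeekWindow.for_week(profile.program_start, k)
            try:
                messages[pid].append(compose_week(
                    records, window, profile, history, bank, global_seed))
            except Exception as exc:  # collect and continue, per contract
                errors.append(f"{pid} week {k}: {exc}")
                logger.warning("participant %s week %d failed: %s", pid, k, exc)

    result = TrialResult(
        global_seed=global_seed,
        n_weeks=n_weeks if n_weeks is not None else 0,
        messages=messages, histories=histories, errors=errors,
        report=_cohort_report(messages, histories))
    if outdir is not None:
        _write_outputs(result, cohort, Path(outdir))
    return result


def _write_outputs(result: TrialResult,
                   cohort: Sequence[tuple[ParticipantProfile, list[DailyRecord]]],
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = {p.participant_id: p for p, _ in cohort}
    with open(outdir / "audits.jsonl", "w") as audit_fh, \
            open(outdir / "manifests.jsonl", "w") as manifest_fh:
        for pid, msgs in result.messages.items():
            profile = profiles[pid]
            lines = []
            for m in msgs:
                window = WeekWindow.for_week(profile.program_start, m.week_index)
                lines.append(f"=== Week {m.week_index} ===\n"
                             + render_message(m) + "\n")
                audit_fh.write(json.dumps({
                    "participant_id": pid, "week_index": m.week_index,
                    "kind": m.kind.value,
                    "audit": m.audit.model_dump()}) + "\n")
                manifest_fh.write(json.dumps(
                    delivery_manifest(m, window)) + "\n")
            (outdir / f"messages_{pid}.txt").write_text("\n".join(lines))
            table = weekly_variables_table(
                result.histories[pid].weekly_variables_log, pid)
            table.to_csv(outdir / f"variables_{pid}.csv", index=False)
    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True))
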