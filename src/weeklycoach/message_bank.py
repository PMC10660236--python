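"""Message banks and the criteria language that selects from them.

A message bank is an externalized YAML (or JSON) document holding every
piece of coaching-message content: weight-feedback messages, behavioral
themes with per-tier selection weights, parent subcomponents, targeted
feedback, milestone texts, the self-weigh reminder and rescue check-in
texts.  Content is configuration; the engine is the machinery.

Messages carry *criteria*: conjunctions of simple comparisons against the
weekly tailoring variables and the participant profile.  The language is
deliberately conjunction-only so that matching stays auditable and the
fallback-coverage guarantee can be checked exhaustively over a
discretized state grid (:func:`check_coverage`).
"""

from __future__ import annotations

import enum
import itertools
import json
import re
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator

from .domain_model import (
    CumPctBand,
    Domain,
    Intent,
    Milestone,
    ParticipantProfile,
    Trailing3Summary,
    ValidationError,
    WeeklyVariables,
    WeightCategory,
)
from .weekly_aggregation import (
    compute_calorie_range,
    cum_pct_band,
    summarize_trailing3,
)

__all__ = [
    "CriterionOp",
    "Criterion",
    "WeightMessage",
    "ProgressTier",
    "Theme",
    "TargetedSlot",
    "ParentMessage",
    "TargetedMessage",
    "MessageBank",
    "BankError",
    "load_bank",
    "default_bank_path",
    "match_criteria",
    "build_state",
    "signature_key",
    "enumerate_signatures",
    "check_coverage",
    "CoverageReport",
    "default_state_grid",
    "PLACEHOLDER_WHITELIST",
    "DECLARED_VARIABLES",
]


class BankError(ValidationError):
    """Raised when a message bank violates its schema or an invariant."""


class CriterionOp(str, enum.Enum):
    LT = "LT"
    LE = "LE"
    EQ = "EQ"
    GE = "GE"
    GT = "GT"
    IN = "IN"
    BETWEEN = "BETWEEN"
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"


class ProgressTier(str, enum.Enum):
    """Coarse weight-loss progress level driving theme probabilities."""

    DECLINING = "DECLINING"
    FLAT = "FLAT"
    IMPROVING = "IMPROVING"


class TargetedSlot(str, enum.Enum):
    """Placeholder at the end of a parent subcomponent: which targeted
    feedback type (if any) to append."""

    NONE = "NONE"
    REINFORCEMENT = "REINFORCEMENT"
    STRATEGY = "STRATEGY"


#: Every variable a criterion may name, mapped to its kind.  "enum" values
#: compare as their string codes; "optional" numerics may be absent, in
#: which case every comparison except PRESENT/ABSENT is false.
DECLARED_VARIABLES: dict[str, str] = {
    "week_index": "int",
    "weight_change": "optional_float",
    "weight_category": "enum",
    "cum_pct_change": "optional_float",
    "cum_pct_band": "enum",
    "days_self_weighed": "int",
    "mvpa_minutes": "float",
    "activity_tracking_days": "int",
    "avg_calorie_intake": "optional_float",
    "days_in_range": "int",
    "days_above_range": "int",
    "days_below_range": "int",
    "monitoring_days": "int",
    "app_used": "bool",
    "trailing3_net_change": "optional_float",
    "trailing3_summary": "enum",
    "intent": "enum",
    "calorie_goal": "float",
    "activity_goal": "float",
}

#: Variables weight-feedback criteria may reference: past-week category,
#: the trailing three-week trend, cumulative percent change, and intent.
WEIGHT_CRITERIA_VARIABLES = {
    "weight_category", "trailing3_summary", "trailing3_net_change",
    "cum_pct_band", "cum_pct_change", "intent",
}

#: Placeholders message templates may interpolate: summary-box behavioral
#: variables and program goals only.  Weight values never appear outside
#: the summary box, so no weight variable is templatable.
PLACEHOLDER_WHITELIST = {
    "days_self_weighed", "mvpa_minutes", "activity_tracking_days",
    "avg_calorie_intake", "days_in_range", "days_above_range",
    "days_below_range", "monitoring_days", "calorie_goal",
    "calorie_range_low", "calorie_range_high", "activity_goal",
}

_PLACEHOLDER_RE = re.compile(r"\{([^{}]*)\}")


def _check_template(text: str, where: str) -> None:
    for name in _PLACEHOLDER_RE.findall(text):
        if name not in PLACEHOLDER_WHITELIST:
            raise BankError(
                f"{where}: placeholder {{{name}}} is not whitelisted "
                f"(allowed: {sorted(PLACEHOLDER_WHITELIST)})")


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

class Criterion(BaseModel):
    """One comparison against a named state variable.

    ``value`` is a scalar for the ordering ops and EQ, a list for IN, an
    ordered inclusive ``[low, high]`` pair for BETWEEN, and unused for
    PRESENT/ABSENT.
    """

    model_config = {"frozen": True}

    var: str
    op: CriterionOp
    value: Any = None

    @field_validator("var")
    @classmethod
    def _known_variable(cls, v: str) -> str:
        if v not in DECLARED_VARIABLES:
            raise ValueError(f"unknown variable {v!r}")
        return v

    def model_post_init(self, __context: Any) -> None:
        if self.op == CriterionOp.BETWEEN:
            if (not isinstance(self.value, (list, tuple)) or len(self.value) != 2
                    or self.value[0] > self.value[1]):
                raise ValueError(
                    f"BETWEEN on {self.var!r} needs an ordered [low, high] pair")
        if self.op == CriterionOp.IN and not isinstance(self.value, (list, tuple, set)):
            raise ValueError(f"IN on {self.var!r} needs a list of values")
        if self.op in (CriterionOp.PRESENT, CriterionOp.ABSENT) and self.value is not None:
            raise ValueError(f"{self.op.value} on {self.var!r} takes no value")

    def evaluate(self, state: Mapping[str, Any]) -> bool:
        """Evaluate against a state mapping; absent values compare false."""
        if self.var not in state:
            raise ValidationError(f"variable {self.var!r} not resolvable in state")
        actual = state[self.var]
        if isinstance(actual, enum.Enum):
            actual = actual.value
        op = self.op
        if op == CriterionOp.PRESENT:
            return actual is not None
        if op == CriterionOp.ABSENT:
            return actual is None
        if actual is None:
            return False
        if op == CriterionOp.EQ:
            return actual == self.value
        if op == CriterionOp.IN:
            return actual in self.value
        if op == CriterionOp.BETWEEN:
            return self.value[0] <= actual <= self.value[1]
        if op == CriterionOp.LT:
            return actual < self.value
        if op == CriterionOp.LE:
            return actual <= self.value
        if op == CriterionOp.GE:
            return actual >= self.value
        if op == CriterionOp.GT:
            return actual > self.value
        raise AssertionError(op)


def match_criteria(criteria: Sequence[Criterion],
                   state: Mapping[str, Any]) -> bool:
    """Conjunction semantics: all criteria hold (an empty list always matches).

    Pure: no state mutation, same inputs give the same output.  Unknown
    variable names are a load-time error, never a match-time surprise.
    """
    return all(c.evaluate(state) for c in criteria)


def build_state(variables: WeeklyVariables,
                profile: ParticipantProfile) -> dict[str, Any]:
    """Flatten weekly variables + profile + derived fields into a criteria state."""
    state = {
        "week_index": variables.week_index,
        "weight_change": variables.weight_change,
        "weight_category": variables.weight_category.value,
        "cum_pct_change": variables.cum_pct_change,
        "cum_pct_band": cum_pct_band(variables.cum_pct_change).value,
        "days_self_weighed": variables.days_self_weighed,
        "mvpa_minutes": variables.mvpa_minutes,
        "activity_tracking_days": variables.activity_tracking_days,
        "avg_calorie_intake": variables.avg_calorie_intake,
        "days_in_range": variables.days_in_range,
        "days_above_range": variables.days_above_range,
        "days_below_range": variables.days_below_range,
        "monitoring_days": variables.monitoring_days,
        "app_used": variables.app_used,
        "trailing3_net_change": variables.trailing3_net_change,
        "trailing3_summary": summarize_trailing3(
            variables.trailing3_categories,
            variables.trailing3_net_change).value,
        "intent": profile.intent.value,
        "calorie_goal": profile.calorie_goal,
        "activity_goal": profile.activity_goal,
    }
    return state


def signature_key(state: Mapping[str, Any]) -> str:
    """Weight-criteria signature: the discretized tuple the habituation rule
    tracks (past-week category, trailing trend, cumulative band, intent)."""
    return "|".join([str(state["weight_category"]),
                     str(state["trailing3_summary"]),
                     str(state["cum_pct_band"]),
                     str(state["intent"])])


# Representative numeric value per cumulative band, used when enumerating
# signature states for bank validation.
_BAND_REPRESENTATIVE = {
    CumPctBand.LE_NEG10: -12.0,
    CumPctBand.NEG10_NEG5: -7.0,
    CumPctBand.NEG5_NEG2: -3.5,
    CumPctBand.NEG2_0: -1.0,
    CumPctBand.POS: 2.0,
}
_TRAILING_REPRESENTATIVE = {
    Trailing3Summary.ALL_LOSS: -2.0,
    Trailing3Summary.ALL_GAIN: 2.0,
    Trailing3Summary.MIXED_LOSS: -1.0,
    Trailing3Summary.MIXED_GAIN: 1.0,
    Trailing3Summary.FLAT: 0.0,
    Trailing3Summary.UNKNOWN: None,
}
_CATEGORY_REPRESENTATIVE = {
    WeightCategory.LOSS: -1.0,
    WeightCategory.MAINTENANCE: 0.0,
    WeightCategory.GAIN: 1.0,
    WeightCategory.UNKNOWN: None,
}


def enumerate_signatures() -> list[dict[str, Any]]:
    """All weight-criteria signature states reachable on a weighed-in week.

    The participant weighed at least once, so the cumulative band is never
    UNKNOWN; the past-week category may still be UNKNOWN (previous week
    had no weigh-in).  Numeric fields carry band representatives so that
    raw-valued criteria also evaluate.
    """
    states = []
    for cat, trail, band, intent in itertools.product(
            WeightCategory, Trailing3Summary,
            [b for b in CumPctBand if b != CumPctBand.UNKNOWN], Intent):
        states.append({
            "weight_category": cat.value,
            "weight_change": _CATEGORY_REPRESENTATIVE[cat],
            "trailing3_summary": trail.value,
            "trailing3_net_change": _TRAILING_REPRESENTATIVE[trail],
            "cum_pct_band": band.value,
            "cum_pct_change": _BAND_REPRESENTATIVE[band],
            "intent": intent.value,
        })
    return states


# ---------------------------------------------------------------------------
# Bank entry types
# ---------------------------------------------------------------------------

class WeightMessage(BaseModel):
    """Weight-feedback message, selected by past-week and trend criteria."""

    model_config = {"frozen": True}

    id: str
    criteria: list[Criterion] = Field(default_factory=list)
    text: str

    @field_validator("criteria")
    @classmethod
    def _weight_vars_only(cls, v: list[Criterion]) -> list[Criterion]:
        for c in v:
            if c.var not in WEIGHT_CRITERIA_VARIABLES:
                raise ValueError(
                    f"weight-message criteria may only reference "
                    f"{sorted(WEIGHT_CRITERIA_VARIABLES)}, got {c.var!r}")
        return v


class Theme(BaseModel):
    """Tone-setting category for the behavioral component.

    ``weights`` maps each progress tier to a non-negative selection
    weight; a theme with weight 0 for a tier is never drawn at that tier.
    """

    model_config = {"frozen": True}

    id: str
    label: str
    tone: str = ""
    weights: dict[ProgressTier, float]

    @field_validator("weights")
    @classmethod
    def _full_nonnegative(cls, v: dict[ProgressTier, float]) -> dict[ProgressTier, float]:
        missing = set(ProgressTier) - set(v)
        if missing:
            raise ValueError(f"missing tier weights: {sorted(t.value for t in missing)}")
        if any(w < 0 for w in v.values()):
            raise ValueError("theme weights must be non-negative")
        return v


class ParentMessage(BaseModel):
    """Parent behavioral subcomponent: one theme, exactly one behavioral
    prescription (domain), data criteria, and a targeted-feedback slot."""

    model_config = {"frozen": True}

    id: str
    theme_id: str
    domain: Domain
    criteria: list[Criterion] = Field(default_factory=list)
    text: str
    targeted_slot: TargetedSlot = TargetedSlot.NONE
    is_fallback: bool = False


class TargetedMessage(BaseModel):
    """Domain-matched closing sentence: reinforcement or a strategy tip."""

    model_config = {"frozen": True}

    id: str
    domain: Domain
    type: TargetedSlot
    text: str

    @field_validator("type")
    @classmethod
    def _not_none(cls, v: TargetedSlot) -> TargetedSlot:
        if v == TargetedSlot.NONE:
            raise ValueError("targeted message type must be REINFORCEMENT or STRATEGY")
        return v


class MessageBank(BaseModel):
    """Validated collection of all message content.

    Validation enforces every structural invariant: unique ids, resolvable
    theme references, at least two weight messages per reachable criteria
    signature (so the habituation rule can always vary the message), at
    least two positively weighted themes per tier (so the no-consecutive-
    theme rule is always satisfiable), a fallback parent per theme, a
    targeted message for every (domain, type) pair, and whitelisted
    template placeholders throughout.
    """

    bank_schema: int = 1
    weight_messages: list[WeightMessage]
    themes: list[Theme]
    parent_messages: list[ParentMessage]
    targeted_messages: list[TargetedMessage]
    milestone_texts: dict[Milestone, str]
    no_weigh_reminder: str
    rescue_checkin_texts: list[str]

    def model_post_init(self, __context: Any) -> None:
        self._validate_ids()
        self._validate_theme_weights()
        self._validate_parents()
        self._validate_targeted()
        self._validate_weight_signatures()
        self._validate_templates()
        self._validate_rescue()

    # -- invariant checks ---------------------------------------------------

    def _validate_ids(self) -> None:
        for kind, entries in [("weight_messages", self.weight_messages),
                              ("themes", self.themes),
                              ("parent_messages", self.parent_messages),
                              ("targeted_messages", self.targeted_messages)]:
            ids = [e.id for e in entries]
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise BankError(f"{kind}: duplicate ids {sorted(dupes)}")

    def _validate_theme_weights(self) -> None:
        if len(self.themes) < 2:
            raise BankError(
                "at least 2 themes are required: with a single theme the "
                "no-consecutive-repeat rule is unsatisfiable")
        for tier in ProgressTier:
            positive = [t.id for t in self.themes if t.weights[tier] > 0]
            if len(positive) < 2:
                raise BankError(
                    f"tier {tier.value}: need >= 2 themes with positive weight "
                    f"so the no-consecutive-repeat rule is satisfiable, "
                    f"got {positive}")

    def _validate_parents(self) -> None:
        theme_ids = {t.id for t in self.themes}
        for p in self.parent_messages:
            if p.theme_id not in theme_ids:
                raise BankError(
                    f"parent_messages[{p.id}]: dangling theme_id {p.theme_id!r}")
        for t in self.themes:
            fallbacks = [p for p in self.parent_messages
                         if p.theme_id == t.id and p.is_fallback]
            if not fallbacks:
                raise BankError(f"theme {t.id!r} has no fallback parent message")

    def _validate_targeted(self) -> None:
        slots = {TargetedSlot.REINFORCEMENT, TargetedSlot.STRATEGY}
        have = {(m.domain, m.type) for m in self.targeted_messages}
        for domain, slot in itertools.product(Domain, slots):
            if (domain, slot) not in have:
                raise BankError(
                    f"no targeted message for (domain={domain.value}, "
                    f"type={slot.value})")

    def _validate_weight_signatures(self) -> None:
        for state in enumerate_signatures():
            matching = [m.id for m in self.weight_messages
                        if match_criteria(m.criteria, state)]
            if len(matching) < 2:
                raise BankError(
                    f"weight-message signature {signature_key(state)} is matched "
                    f"by {len(matching)} message(s); need >= 2 so repeated weeks "
                    f"at the same criteria receive different messages")

    def _validate_templates(self) -> None:
        for m in self.weight_messages:
            _check_template(m.text, f"weight_messages[{m.id}]")
        for p in self.parent_messages:
            _check_template(p.text, f"parent_messages[{p.id}]")
        for t in self.targeted_messages:
            _check_template(t.text, f"targeted_messages[{t.id}]")
        _check_template(self.no_weigh_reminder, "no_weigh_reminder")
        for ms, text in self.milestone_texts.items():
            _check_template(text, f"milestone_texts[{ms.value}]")
        missing = set(Milestone) - set(self.milestone_texts)
        if missing:
            raise BankError(
                f"milestone_texts missing {sorted(m.value for m in missing)}")

    def _validate_rescue(self) -> None:
        if not self.rescue_checkin_texts:
            raise BankError("rescue_checkin_texts must not be empty")
        for i, text in enumerate(self.rescue_checkin_texts):
            if _PLACEHOLDER_RE.search(text) or re.search(r"\d", text):
                raise BankError(
                    f"rescue_checkin_texts[{i}]: check-in texts must not "
                    f"reference progress (no placeholders, no numerals)")

    # -- lookups ------------------------------------------------------------

    def theme(self, theme_id: str) -> Theme:
        for t in self.themes:
            if t.id == theme_id:
                return t
        raise KeyError(theme_id)

    def parents_of_theme(self, theme_id: str) -> list[ParentMessage]:
        return [p for p in self.parent_messages if p.theme_id == theme_id]

    def targeted_for(self, domain: Domain,
                     slot: TargetedSlot) -> list[TargetedMessage]:
        return [m for m in self.targeted_messages
                if m.domain == domain and m.type == slot]


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def default_bank_path() -> Path:
    """Path of the bundled default message bank."""
    return Path(__file__).parent / "data" / "default_bank.yaml"


def load_bank(path: str | Path | None = None) -> MessageBank:
    """Load and fully validate a message bank (YAML, or JSON-equivalent).

    Idempotent: loading the same file twice yields equal banks.  Schema
    violations raise :class:`BankError` naming the offending entry.
    """
    path = Path(path) if path is not None else default_bank_path()
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise BankError(f"{path}: bank file must be a mapping")
    if data.get("bank_schema") != 1:
        raise BankError(f"{path}: unsupported bank_schema "
                        f"{data.get('bank_schema')!r} (expected 1)")
    try:
        return MessageBank.model_validate(data)
    except BankError:
        raise
    except Exception as exc:
        raise BankError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Coverage checking
# ---------------------------------------------------------------------------

class CoverageReport(BaseModel):
    """Findings of :func:`check_coverage`."""

    n_states: int
    uncovered: list[tuple[str, str]] = Field(default_factory=list)  # (theme, state)
    unreachable_parents: list[str] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.uncovered and not self.unreachable_parents


def _describe(state: Mapping[str, Any]) -> str:
    return ",".join(f"{k}={state[k]}" for k in sorted(state))


def default_state_grid(calorie_goal: float = 1800.0,
                       activity_goal: float = 150.0) -> Iterable[dict[str, Any]]:
    """The documented discretized grid over the weekly-variable state space.

    Each count variable takes 0/4/7 (the calorie-day triple constrained to
    sum to at most 7), each numeric takes its boundary-straddling
    representatives, each optional field appears both present and absent,
    and every enum takes all values with its tied numeric representative.
    Yields plain state dicts lazily; the full grid has ~330k states.
    """
    low, high = compute_calorie_range(calorie_goal)
    counts = (0, 4, 7)
    cal_triples = [(i, a, b) for i in counts for a in counts for b in counts
                   if i + a + b <= 7]
    avg_cals = (None, low - 200, (low + high) / 2, high + 300)
    mvpas = (0.0, activity_goal / 2, 2 * activity_goal)
    cum_bands = list(CumPctBand)
    for (cat, dsw, atd, mvpa, avg, (din, dab, dbl), app, band, trail,
         intent) in itertools.product(
            WeightCategory, counts, counts, mvpas, avg_cals, cal_triples,
            (False, True), cum_bands, Trailing3Summary, Intent):
        yield {
            "week_index": 5,
            "weight_category": cat.value,
            "weight_change": _CATEGORY_REPRESENTATIVE[cat],
            "cum_pct_band": band.value,
            "cum_pct_change": _BAND_REPRESENTATIVE.get(band),
            "days_self_weighed": dsw,
            "mvpa_minutes": mvpa,
            "activity_tracking_days": atd,
            "avg_calorie_intake": avg,
            "days_in_range": din,
            "days_above_range": dab,
            "days_below_range": dbl,
            "monitoring_days": din + dab,
            "app_used": app,
            "trailing3_summary": trail.value,
            "trailing3_net_change": _TRAILING_REPRESENTATIVE[trail],
            "intent": intent.value,
            "calorie_goal": calorie_goal,
            "activity_goal": activity_goal,
        }


def check_coverage(bank: MessageBank,
                   state_grid: Iterable[Mapping[str, Any]] | None = None,
                   max_uncovered: int = 25) -> CoverageReport:
    """Verify the fallback guarantee over a state grid.

    For every theme and every grid state at least one parent message must
    match (participants must always meet the criteria of some parent).
    Parents matched by no grid state are reported as unreachable.  At most
    ``max_uncovered`` uncovered pairs are listed verbatim; the count in
    the report is exact regardless.
    """
    if state_grid is None:
        state_grid = default_state_grid()
    by_theme = {t.id: bank.parents_of_theme(t.id) for t in bank.themes}
    # Pre-extract criteria lists once; evaluation early-exits per theme as
    # soon as one parent matches, except that each parent must be evaluated
    # until it has matched at least one state (reachability).
    matched_ever: set[str] = set()
    n_parents = len(bank.parent_messages)
    uncovered: list[tuple[str, str]] = []
    n_uncovered = 0
    n_states = 0
    for state in state_grid:
        n_states += 1
        for theme_id, parents in by_theme.items():
            covered = False
            for p in parents:
                if covered and p.id in matched_ever:
                    continue
                if match_criteria(p.criteria, state):
                    covered = True
                    if len(matched_ever) < n_parents:
                        matched_ever.add(p.id)
            if not covered:
                n_uncovered += 1
                if len(uncovered) < max_uncovered:
                    uncovered.append((theme_id, _describe(state)))
    report = CoverageReport(
        n_states=n_states,
        uncovered=uncovered,
        unreachable_parents=sorted(
            p.id for p in bank.parent_messages if p.id not in matched_ever),
    )
    # Keep the exact count even when the listing is truncated.
    if n_uncovered > len(uncovered):
        report = report.model_copy(update={"uncovered": uncovered + [
            ("...", f"{n_uncovered - len(uncovered)} further uncovered states")]})
    return report
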