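"""Bisphosphonate treatment duration, monitoring and pause rules.

Oral bisphosphonates (alendronate, risedronate, ibandronate) are planned
for at least 5 years, annual intravenous zoledronate for at least 3 years.
Either is extended — to at least 10 or 6 years respectively — when the
patient was >= 70 at the start of treatment, has a previous hip or
vertebral fracture, is on high-dose oral glucocorticoids, or fractures
during the initial treatment period.  If no extension criterion holds at
the baseline review, a temporary treatment pause can be considered, with
FRAX reassessment after a drug-specific offset interval (18 months for
risedronate and ibandronate, 2 years for alendronate, 3 years for
zoledronate — matching how quickly each drug's effect wears off).  A new
fracture during a pause prompts reassessment and restart; a fracture on
treatment prompts an adherence review (poor adherence: less than 80% of
treatment taken correctly) and investigation for secondary causes.

Plans express *minimum* durations: the planner emits review dates, never a
stop date.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Drug",
    "Route",
    "TreatmentEvent",
    "TreatmentContext",
    "TreatmentPlan",
    "Directive",
    "ADHERENCE_THRESHOLD_PCT",
    "planned_duration",
    "pause_reassessment_interval",
    "on_event",
    "adherence_flag",
]


class Drug(str, enum.Enum):
    ALENDRONATE = "alendronate"
    RISEDRONATE = "risedronate"
    IBANDRONATE = "ibandronate"
    ZOLEDRONATE = "zoledronate"


class Route(str, enum.Enum):
    ORAL = "oral"
    INTRAVENOUS = "intravenous"


_DRUG_ROUTE = {
    Drug.ALENDRONATE: Route.ORAL,
    Drug.RISEDRONATE: Route.ORAL,
    Drug.IBANDRONATE: Route.ORAL,
    Drug.ZOLEDRONATE: Route.INTRAVENOUS,
}

#: FRAX reassessment interval after stopping, by drug (months).
_PAUSE_INTERVAL_MONTHS = {
    Drug.RISEDRONATE: 18,
    Drug.IBANDRONATE: 18,
    Drug.ALENDRONATE: 24,
    Drug.ZOLEDRONATE: 36,
}

#: Minimum / extended planned durations (years) by route.
_BASELINE_YEARS = {Route.ORAL: 5, Route.INTRAVENOUS: 3}
_EXTENDED_YEARS = {Route.ORAL: 10, Route.INTRAVENOUS: 6}

#: Poor adherence: less than 80% of treatment taken correctly.
ADHERENCE_THRESHOLD_PCT = 80.0


class TreatmentEvent(str, enum.Enum):
    NEW_FRACTURE_ON_PAUSE = "new_fracture_on_pause"
    NEW_FRACTURE_ON_TREATMENT = "new_fracture_on_treatment"
    PAUSE_ELAPSED = "pause_elapsed"


@dataclass(frozen=True)
class TreatmentContext:
    """Inputs to duration planning for one bisphosphonate course."""

    drug: Drug
    route: Route
    age_at_start: float
    prior_hip_or_vertebral_fracture: bool = False
    gc_high_dose: bool = False  # >= 7.5 mg/day prednisolone-equivalent over 3 months
    fracture_on_treatment: bool = False
    adherence_pct: float | None = None

    def __post_init__(self) -> None:
        if _DRUG_ROUTE[Drug(self.drug)] is not Route(self.route):
            raise ValueError(
                f"inconsistent drug/route pairing: {self.drug} is given "
                f"{_DRUG_ROUTE[Drug(self.drug)].value}, not {Route(self.route).value}"
            )


@dataclass
class TreatmentPlan:
    """A planned minimum treatment duration with review scheduling."""

    drug: Drug
    route: Route
    baseline_duration_years: int
    extended: bool
    extended_duration_years: int | None
    extension_reasons: list[str]
    pause_reassessment_months: int
    notes: list[str] = field(default_factory=list)

    @property
    def planned_years(self) -> int:
        return self.extended_duration_years if self.extended else self.baseline_duration_years

    def to_dict(self) -> dict:
        return {
            "drug": self.drug.value,
            "route": self.route.value,
            "baseline_duration_years": self.baseline_duration_years,
            "extended": self.extended,
            "extended_duration_years": self.extended_duration_years,
            "extension_reasons": list(self.extension_reasons),
            "pause_reassessment_months": self.pause_reassessment_months,
            "notes": list(self.notes),
        }


@dataclass(frozen=True)
class Directive:
    """Actions directed in response to a treatment-course event."""

    actions: tuple[str, ...]
    extension_trigger: bool = False


def pause_reassessment_interval(drug: Drug | str) -> int:
    """Months after stopping at which FRAX reassessment is due, by drug."""
    try:
        return _PAUSE_INTERVAL_MONTHS[Drug(drug)]
    except ValueError as exc:
        raise ValueError(f"unsupported drug for pause planning: {drug!r}") from exc


def planned_duration(ctx: TreatmentContext) -> TreatmentPlan:
    """Minimum planned duration, extension criteria and review interval.

    Oral route: at least 5 years, at least 10 when any extension criterion
    holds.  Intravenous (annual zoledronate): at least 3 years, at least 6.
    Every extension is traceable to its triggering criterion.
    """
    route = Route(ctx.route)
    baseline = _BASELINE_YEARS[route]
    reasons: list[str] = []
    if ctx.age_at_start >= 70:
        reasons.append("age >= 70 years when the bisphosphonate was started")
    if ctx.prior_hip_or_vertebral_fracture:
        reasons.append("previous history of hip or vertebral fracture")
    if ctx.gc_high_dose:
        reasons.append(
            "oral glucocorticoids >= 7.5 mg/day prednisolone-equivalent"
        )
    if ctx.fracture_on_treatment:
        reasons.append(
            f"one or more fragility fractures during the first {baseline} years of treatment"
        )
    extended = bool(reasons)
    plan = TreatmentPlan(
        drug=Drug(ctx.drug),
        route=route,
        baseline_duration_years=baseline,
        extended=extended,
        extended_duration_years=_EXTENDED_YEARS[route] if extended else None,
        extension_reasons=reasons,
        pause_reassessment_months=pause_reassessment_interval(ctx.drug),
    )
    plan.notes.append(
        "durations are minimums; reassess fracture risk with FRAX at the "
        "planned review, and consider a temporary treatment pause only if no "
        "extension criterion holds"
    )
    if extended and plan.extended_duration_years == 10:
        plan.notes.append(
            "after 10 years of bisphosphonate treatment, management should be "
            "individualised"
        )
    return plan


def on_event(plan: TreatmentPlan, event: TreatmentEvent | str) -> Directive:
    """Directive for an event during or after a bisphosphonate course."""
    event = TreatmentEvent(event)
    if event is TreatmentEvent.NEW_FRACTURE_ON_PAUSE:
        return Directive(actions=("reassess_frax", "restart_treatment"))
    if event is TreatmentEvent.NEW_FRACTURE_ON_TREATMENT:
        return Directive(
            actions=("review_adherence", "investigate_secondary_causes"),
            extension_trigger=True,
        )
    if event is TreatmentEvent.PAUSE_ELAPSED:
        return Directive(actions=("reassess_frax",))
    raise ValueError(f"unhandled treatment event: {event!r}")  # pragma: no cover


def adherence_flag(adherence_pct: float) -> bool:
    """True when adherence is poor: less than 80% of treatment taken correctly."""
    if not 0 <= adherence_pct <= 100:
        raise ValueError(f"adherence must be in [0, 100], got {adherence_pct}")
    return adherence_pct < ADHERENCE_THRESHOLD_PCT
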