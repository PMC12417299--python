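"""Fracture-risk categorisation and management actions.

Classifies a patient into low / intermediate / high / very-high fracture
risk from their (adjusted) FRAX probabilities and the age-dependent
thresholds, applies the clinical overrides that can raise a patient to very
high risk regardless of probability, maps the category to a management
action, decides whether vertebral fracture assessment (VFA) is indicated,
and — when the glucocorticoid input is set — produces the dual medium-dose /
high-dose assessment points shown on the NOGG graphs.

Classification bands differ by whether femoral-neck BMD was included in the
FRAX calculation.  Without BMD the lower and upper assessment thresholds
bound an *intermediate* band in which BMD measurement is indicated; once
BMD is included only the intervention and very-high-risk thresholds matter
and the intermediate category does not exist.  A probability exactly equal
to a threshold falls in the higher (treatment-favouring) category.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .adjustments import (
    AdjustmentLedger,
    FraxProbabilities,
    GlucocorticoidTier,
    Sex,
    select_dominant,
)
from .thresholds import Outcome, Thresholds, ThresholdSet, anchor_table

__all__ = [
    "Category",
    "Action",
    "Diabetes",
    "PatientProfile",
    "RiskAssessment",
    "VERY_HIGH_TSCORE",
    "RECENT_FRACTURE_WINDOW_MONTHS",
    "MULTIPLE_CRF_COUNT",
    "classify_outcome",
    "combine_categories",
    "apply_clinical_overrides",
    "recommend_action",
    "vfa_indicated",
    "assess",
]


class Category(enum.IntEnum):
    """Risk category, ordered so that ``max`` picks the higher risk."""

    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2
    VERY_HIGH = 3

    @property
    def token(self) -> str:
        return self.name.lower()

    @classmethod
    def from_token(cls, token: str) -> "Category":
        return cls[token.upper()]


class Action(str, enum.Enum):
    LIFESTYLE_ADVICE = "lifestyle_advice"
    MEASURE_BMD_THEN_REASSESS = "measure_bmd_then_reassess"
    OFFER_TREATMENT = "offer_treatment"
    OFFER_TREATMENT_CONSIDER_REFERRAL = "offer_treatment_consider_referral"


class Diabetes(str, enum.Enum):
    NONE = "none"
    TYPE1 = "type1"
    TYPE2 = "type2"


#: BMD T-score at or below which risk is very high regardless of probability.
VERY_HIGH_TSCORE = -3.5
#: "Recent" fracture window, months (imminent-risk period of ~2 years).
RECENT_FRACTURE_WINDOW_MONTHS = 24
#: Number of clinical risk-factor flags counted as "multiple" when combined
#: with a recent fragility fracture.  The guideline gives no count; this is
#: an explicit, overridable operationalisation.
MULTIPLE_CRF_COUNT = 3


class PatientProfile(BaseModel):
    """Clinical risk-factor flags consumed by adjustments and categorisation.

    Optional measurements default to ``None`` (absent), boolean risk factors
    to ``False``; absence is never treated as risk-factor-present.
    """

    age: float = Field(gt=0)
    sex: Sex = Sex.FEMALE
    gc_dose_tier: GlucocorticoidTier = GlucocorticoidTier.NONE
    ls_tscore: Optional[float] = None
    fn_tscore: Optional[float] = None
    min_tscore_override: Optional[float] = None
    tbs_sd_decrease: Optional[float] = None
    hal_sd_diff: Optional[float] = None
    recurrent_falls: bool = False
    diabetes: Diabetes = Diabetes.NONE
    parkinsons: bool = False
    prior_fragility_fracture: bool = False
    recent_mof_months: Optional[float] = Field(default=None, ge=0)
    vertebral_fracture_count: int = Field(default=0, ge=0)
    recent_vertebral_fracture: bool = False
    height_loss_cm: Optional[float] = Field(default=None, ge=0)
    kyphosis: bool = False
    acute_back_pain: bool = False
    bmd_practical: bool = True
    bmd_available: bool = True
    reliable_high_spine_bmd: bool = False

    @model_validator(mode="after")
    def _recent_vf_implies_count(self) -> "PatientProfile":
        if self.recent_vertebral_fracture and self.vertebral_fracture_count < 1:
            raise ValueError(
                "recent_vertebral_fracture implies vertebral_fracture_count >= 1"
            )
        return self

    @property
    def min_tscore(self) -> Optional[float]:
        """Lowest available BMD T-score (explicit override wins)."""
        if self.min_tscore_override is not None:
            return self.min_tscore_override
        scores = [t for t in (self.ls_tscore, self.fn_tscore) if t is not None]
        return min(scores) if scores else None

    def risk_factor_count(self) -> int:
        """Number of set clinical risk-factor flags (for the 'multiple CRF' rule)."""
        flags = [
            self.recurrent_falls,
            self.diabetes is not Diabetes.NONE,
            self.parkinsons,
            self.prior_fragility_fracture,
            self.vertebral_fracture_count >= 1,
            self.kyphosis,
            self.height_loss_cm is not None and self.height_loss_cm >= 4,
            self.gc_dose_tier is not GlucocorticoidTier.NONE,
        ]
        return sum(flags)


@dataclass
class RiskAssessment:
    """Full per-patient output of the assessment pipeline."""

    mof_category: Category
    hip_category: Category
    overall_category: Category
    action: Action
    referral_reasons: list[str] = field(default_factory=list)
    ledger: AdjustmentLedger | None = None
    dual_points: Optional[tuple["RiskAssessment", "RiskAssessment"]] = None
    vfa_indicated: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "mof_category": self.mof_category.token,
            "hip_category": self.hip_category.token,
            "overall_category": self.overall_category.token,
            "action": self.action.value,
            "referral_reasons": list(self.referral_reasons),
            "vfa_indicated": self.vfa_indicated,
            "notes": list(self.notes),
            "ledger": self.ledger.to_dict() if self.ledger else None,
        }
        if self.dual_points is not None:
            d["dual_points"] = {
                "medium_dose": self.dual_points[0].to_dict(),
                "high_dose": self.dual_points[1].to_dict(),
            }
        else:
            d["dual_points"] = None
        return d


def classify_outcome(
    prob: float, thresholds: Thresholds, bmd_included: bool
) -> Category:
    """Risk category of one probability against one outcome's thresholds.

    With BMD included: below IT low, [IT, VHRT) high, >= VHRT very high (no
    intermediate band).  Without BMD: below LAT low, [LAT, UAT) intermediate,
    [UAT, VHRT) high, >= VHRT very high.  Boundary values take the higher
    category.
    """
    lat, it, uat, vhrt = thresholds
    if not (lat < it < uat < vhrt):
        raise ValueError(f"thresholds must satisfy lat < it < uat < vhrt, got {thresholds}")
    if prob >= vhrt:
        return Category.VERY_HIGH
    if bmd_included:
        return Category.HIGH if prob >= it else Category.LOW
    if prob >= uat:
        return Category.HIGH
    if prob >= lat:
        return Category.INTERMEDIATE
    return Category.LOW


def combine_categories(mof_cat: Category, hip_cat: Category) -> Category:
    """Overall category = the higher of the two outcome categories."""
    return max(mof_cat, hip_cat)


def apply_clinical_overrides(
    category: Category,
    profile: PatientProfile,
    ledger: AdjustmentLedger | None = None,
) -> tuple[Category, list[str]]:
    """Raise to very high risk on the guideline's single-factor indications.

    Triggers: a recent vertebral fracture (within 2 years); >= 2 vertebral
    fractures whenever they occurred; a BMD T-score <= -3.5; high-dose
    glucocorticoids; or an already-high category with a recent major
    osteoporotic fracture plus multiple other clinical risk factors.
    Categories are only ever raised, never lowered.
    """
    reasons: list[str] = []
    if profile.recent_vertebral_fracture:
        reasons.append("recent vertebral fracture (within the last 2 years)")
    if profile.vertebral_fracture_count >= 2:
        reasons.append(">= 2 vertebral fractures")
    mt = profile.min_tscore
    if mt is not None and mt <= VERY_HIGH_TSCORE:
        reasons.append(f"BMD T-score <= {VERY_HIGH_TSCORE}")
    if profile.gc_dose_tier in (GlucocorticoidTier.HIGH, GlucocorticoidTier.VERY_HIGH):
        reasons.append(
            "high-dose glucocorticoids (>= 7.5 mg/day prednisolone-equivalent "
            "over 3 months); refer urgently"
        )
    if (
        category is Category.HIGH
        and profile.recent_mof_months is not None
        and profile.recent_mof_months <= RECENT_FRACTURE_WINDOW_MONTHS
        and profile.risk_factor_count() >= MULTIPLE_CRF_COUNT
    ):
        reasons.append(
            "multiple clinical risk factors with a recent fragility fracture "
            "(high imminent re-fracture risk)"
        )
    if reasons:
        return max(category, Category.VERY_HIGH), reasons
    return category, reasons


def recommend_action(
    category: Category,
    profile: PatientProfile,
    probs: FraxProbabilities | None = None,
    thresholds: dict[Outcome, Thresholds] | None = None,
) -> Action:
    """Map a combined, overridden category to a management action.

    Low risk: lifestyle advice and reassurance.  Intermediate risk: BMD
    measurement then FRAX reassessment where practical; where BMD is
    impractical, treatment is offered if there is a prior fragility fracture
    or the probability already exceeds the intervention threshold, otherwise
    lifestyle advice.  High risk: offer treatment.  Very high risk: offer
    treatment and consider specialist referral.
    """
    if category is Category.VERY_HIGH:
        return Action.OFFER_TREATMENT_CONSIDER_REFERRAL
    if category is Category.HIGH:
        return Action.OFFER_TREATMENT
    if category is Category.INTERMEDIATE:
        if profile.bmd_practical and profile.bmd_available:
            return Action.MEASURE_BMD_THEN_REASSESS
        if profile.prior_fragility_fracture:
            return Action.OFFER_TREATMENT
        if probs is not None and thresholds is not None:
            exceeds_it = (
                probs.mof_pct >= thresholds[Outcome.MOF].it
                or probs.hip_pct >= thresholds[Outcome.HIP].it
            )
            if exceeds_it:
                return Action.OFFER_TREATMENT
        return Action.LIFESTYLE_ADVICE
    return Action.LIFESTYLE_ADVICE


def vfa_indicated(profile: PatientProfile) -> bool:
    """Whether vertebral fracture assessment (lateral spine imaging) is indicated.

    Triggers: height loss >= 4 cm, kyphosis, recent or current long-term
    oral glucocorticoid therapy (any dose tier set), a BMD T-score <= -2.5
    at spine or hip, or acute-onset back pain with any osteoporosis risk
    factor.
    """
    if profile.height_loss_cm is not None and profile.height_loss_cm >= 4:
        return True
    if profile.kyphosis:
        return True
    if profile.gc_dose_tier is not GlucocorticoidTier.NONE:
        return True
    mt = profile.min_tscore
    if mt is not None and mt <= -2.5:
        return True
    if profile.acute_back_pain and profile.risk_factor_count() >= 1:
        return True
    return False


def _classify_both(
    probs: FraxProbabilities, age: float, sets: dict[Outcome, ThresholdSet]
) -> tuple[Category, Category, dict[Outcome, Thresholds]]:
    th = {o: sets[o].at(age) for o in (Outcome.MOF, Outcome.HIP)}
    mof_cat = classify_outcome(probs.mof_pct, th[Outcome.MOF], probs.bmd_included)
    hip_cat = classify_outcome(probs.hip_pct, th[Outcome.HIP], probs.bmd_included)
    return mof_cat, hip_cat, th


def _assess_single(
    profile: PatientProfile,
    probs: FraxProbabilities,
    sets: dict[Outcome, ThresholdSet],
) -> RiskAssessment:
    ledger = select_dominant(probs, profile)
    adjusted = ledger.final
    mof_cat, hip_cat, th = _classify_both(adjusted, profile.age, sets)
    combined = combine_categories(mof_cat, hip_cat)
    overridden, reasons = apply_clinical_overrides(combined, profile, ledger)
    action = recommend_action(overridden, profile, adjusted, th)
    notes = list(ledger.notes)
    if overridden is Category.HIGH and not profile.bmd_available:
        notes.append("obtain a baseline DXA if needed for future monitoring")
    return RiskAssessment(
        mof_category=mof_cat,
        hip_category=hip_cat,
        overall_category=overridden,
        action=action,
        referral_reasons=reasons,
        ledger=ledger,
        vfa_indicated=vfa_indicated(profile),
        notes=notes,
    )


def assess(
    profile: PatientProfile,
    probs: FraxProbabilities,
    sets: dict[Outcome, ThresholdSet] | None = None,
) -> RiskAssessment:
    """Full assessment pipeline for one patient.

    Adjust (dominant-factor rule) -> thresholds at the patient's age for
    both outcomes -> classify each -> combine by maximum -> clinical
    overrides -> management action -> VFA flag.  When the glucocorticoid
    dose tier is set, ``dual_points`` carries the two points shown on the
    NOGG graphs: the assessment at medium dose (the FRAX baseline) and at
    high dose.
    """
    sets = sets if sets is not None else anchor_table()
    try:
        result = _assess_single(profile, probs, sets)
        if profile.gc_dose_tier is not GlucocorticoidTier.NONE:
            medium = _assess_single(
                profile.model_copy(update={"gc_dose_tier": GlucocorticoidTier.MEDIUM}),
                probs,
                sets,
            )
            high = _assess_single(
                profile.model_copy(update={"gc_dose_tier": GlucocorticoidTier.HIGH}),
                probs,
                sets,
            )
            result.dual_points = (medium, high)
        return result
    except (ValueError, KeyError) as exc:  # pragma: no cover - context wrapper
        raise type(exc)(
            f"assessment failed for patient aged {profile.age} ({profile.sex.value}): {exc}"
        ) from exc
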