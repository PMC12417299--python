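"""Arithmetic adjustments to FRAX 10-year fracture probabilities.

FRAX has a fixed input set, so the guideline supplies simple proportional
adjustments for risk information FRAX cannot take directly: glucocorticoid
dose tier, lumbar spine / femoral neck BMD discordance, trabecular bone
score (TBS), hip axis length (HAL) and recurrent falls.  Each adjustment is
applied *as a proportion of the original FRAX probability* (e.g. uplifting
30% by 10% gives 30 x 1.10 = 33%).

When several refinements apply, the guideline says to adjust for the single
most dominant factor.  The glucocorticoid dose adjustment is different in
kind: FRAX assumes a medium dose (2.5-7.5 mg/day prednisolone-equivalent)
whenever the glucocorticoid box is ticked, so the dose-tier multipliers
re-baseline the FRAX output and are applied first, before dominance is
decided among the remaining candidates.

All probabilities are handled on the 0-100 percent scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from pydantic import BaseModel, Field

if TYPE_CHECKING:  # pragma: no cover
    from .categorise import PatientProfile

__all__ = [
    "Sex",
    "GlucocorticoidTier",
    "FraxProbabilities",
    "AdjustmentCandidate",
    "AdjustmentLedger",
    "PROB_CAP",
    "PROB_FLOOR",
    "GC_MULTIPLIERS",
    "proportional_adjust",
    "adjust_glucocorticoid",
    "adjust_spine_discordance",
    "adjust_tbs",
    "adjust_hal",
    "adjust_falls",
    "frax_input_surrogates",
    "select_dominant",
    "round_half_away",
]

#: Adjusted probabilities are capped at 100% ...
PROB_CAP = 100.0
#: ... and floored at a small positive value so log displays stay defined.
PROB_FLOOR = 0.01


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class GlucocorticoidTier(str, enum.Enum):
    """Daily prednisolone-equivalent dose tier.

    none: not on glucocorticoids; low: < 2.5 mg/day; medium: 2.5-7.5 mg/day
    (the FRAX baseline); high: >= 7.5 mg/day; very_high: > 20 mg/day.
    """

    NONE = "none"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


#: (MOF multiplier, hip multiplier) by dose tier.  Medium dose is the FRAX
#: baseline, hence no change; very high dose has no published factor larger
#: than the high-dose one, so the high-dose multipliers are used and an
#: escalation note is attached by the caller.
GC_MULTIPLIERS: dict[GlucocorticoidTier, tuple[float, float]] = {
    GlucocorticoidTier.NONE: (1.0, 1.0),
    GlucocorticoidTier.LOW: (0.80, 0.65),
    GlucocorticoidTier.MEDIUM: (1.0, 1.0),
    GlucocorticoidTier.HIGH: (1.15, 1.20),
    GlucocorticoidTier.VERY_HIGH: (1.15, 1.20),
}

#: Proportional uplift per unit for each refinement rule.
SPINE_DISCORDANCE_PER_TSCORE = 0.10
TBS_PER_SD = 0.30
HAL_PER_SD = 0.30
FALLS_UPLIFT = 0.30


class FraxProbabilities(BaseModel):
    """A FRAX output: 10-year MOF and hip fracture probabilities (percent).

    ``bmd_included`` records whether femoral-neck BMD was an input to the
    FRAX calculation — it decides which classification bands apply
    downstream.  ``hip_pct > mof_pct`` is deliberately allowed (FRAX can
    rarely produce it).
    """

    model_config = {"frozen": True}

    mof_pct: float = Field(ge=0, le=100)
    hip_pct: float = Field(ge=0, le=100)
    bmd_included: bool = False
    age: float = Field(gt=0)
    sex: Sex = Sex.FEMALE

    def replace(self, *, mof_pct: float | None = None, hip_pct: float | None = None) -> "FraxProbabilities":
        return self.model_copy(
            update={
                k: v
                for k, v in {"mof_pct": mof_pct, "hip_pct": hip_pct}.items()
                if v is not None
            }
        )


def _clamp(p: float) -> float:
    return min(max(p, PROB_FLOOR), PROB_CAP)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (school rounding, not banker's)."""
    factor = 10**ndigits
    scaled = x * factor
    import math

    return math.floor(scaled + 0.5) / factor if scaled >= 0 else math.ceil(scaled - 0.5) / factor


def proportional_adjust(prob: float, uplift_fraction: float) -> float:
    """Apply a signed proportional adjustment to a probability (percent).

    ``prob x (1 + uplift_fraction)``, capped at 100.  A 30% probability
    uplifted by +0.10 becomes 33%.
    """
    if not 0 <= prob <= 100:
        raise ValueError(f"probability must be in [0, 100], got {prob}")
    if uplift_fraction <= -1:
        raise ValueError(f"uplift fraction must exceed -1, got {uplift_fraction}")
    return min(prob * (1 + uplift_fraction), PROB_CAP)


def adjust_glucocorticoid(
    probs: FraxProbabilities, dose_tier: GlucocorticoidTier | str
) -> FraxProbabilities:
    """Re-baseline FRAX output by glucocorticoid dose tier.

    Low dose: MOF x 0.80, hip x 0.65.  Medium dose and none: unchanged
    (FRAX already assumes a medium dose when the glucocorticoid input is
    set).  High and very-high dose: MOF x 1.15, hip x 1.20.
    """
    tier = GlucocorticoidTier(dose_tier)
    m_mof, m_hip = GC_MULTIPLIERS[tier]
    return probs.replace(
        mof_pct=_clamp(probs.mof_pct * m_mof), hip_pct=_clamp(probs.hip_pct * m_hip)
    )


def adjust_spine_discordance(
    probs: FraxProbabilities,
    ls_tscore: float,
    fn_tscore: float,
    reliable_high_spine_bmd: bool = False,
) -> FraxProbabilities:
    """Adjust MOF probability for lumbar spine / femoral neck BMD offset.

    MOF changes by 10% per rounded T-score unit of discordance
    ``d = round(fn - ls)`` (positive when the spine is the lower site).
    Downward adjustments (spine higher than hip) are applied only when the
    caller vouches for the spine measurement via ``reliable_high_spine_bmd``;
    a discordantly *high* spine is commonly a degenerative-change artefact.
    Hip probability is unchanged.
    """
    if ls_tscore is None or fn_tscore is None:
        raise ValueError("both lumbar-spine and femoral-neck T-scores are required")
    d = int(round_half_away(fn_tscore - ls_tscore))
    if d < 0 and not reliable_high_spine_bmd:
        return probs  # caution: no downward change without a reliable spine BMD
    return probs.replace(
        mof_pct=_clamp(probs.mof_pct * (1 + SPINE_DISCORDANCE_PER_TSCORE * d))
    )


def adjust_tbs(probs: FraxProbabilities, tbs_sd_decrease: float) -> FraxProbabilities:
    """Adjust MOF probability for trabecular bone score: +30% per SD decrease.

    ``tbs_sd_decrease`` is signed; positive means a TBS below the reference
    (higher risk).  Scaling is linear per SD, not compounded.
    """
    return probs.replace(mof_pct=_clamp(probs.mof_pct * (1 + TBS_PER_SD * tbs_sd_decrease)))


def adjust_hal(probs: FraxProbabilities, hal_sd_diff: float) -> FraxProbabilities:
    """Adjust hip probability for hip axis length: +/-30% per SD difference.

    Positive means a longer hip axis (higher hip fracture risk).
    """
    return probs.replace(hip_pct=_clamp(probs.hip_pct * (1 + HAL_PER_SD * hal_sd_diff)))


def adjust_falls(probs: FraxProbabilities, recurrent_falls: bool) -> FraxProbabilities:
    """Uplift both probabilities by 30% for recurrent falls (>= 2 in the last year)."""
    if not recurrent_falls:
        return probs
    return probs.replace(
        mof_pct=_clamp(probs.mof_pct * (1 + FALLS_UPLIFT)),
        hip_pct=_clamp(probs.hip_pct * (1 + FALLS_UPLIFT)),
    )


def frax_input_surrogates(profile: "PatientProfile") -> dict[str, str]:
    """Pre-FRAX surrogate input flags the guideline mandates.

    Type 1 or 2 diabetes and Parkinson's disease (or related movement
    disorders) are entered into FRAX via the rheumatoid-arthritis input.
    These are advisory outputs: this engine does not run FRAX.
    """
    flags: dict[str, str] = {}
    notes = []
    diabetes = getattr(profile, "diabetes", "none")
    if str(getattr(diabetes, "value", diabetes)) in ("type1", "type2"):
        flags["rheumatoid_arthritis"] = "yes"
    if getattr(profile, "parkinsons", False):
        flags["rheumatoid_arthritis"] = "yes"
        notes.append(
            "Parkinson's disease: the rheumatoid-arthritis surrogate only "
            "partly accounts for the increased fracture risk"
        )
    if notes:
        flags["notes"] = "; ".join(notes)
    return flags


@dataclass
class AdjustmentCandidate:
    """One refinement rule evaluated on the (glucocorticoid-adjusted) input."""

    name: str
    adjusted: FraxProbabilities
    delta: float  # absolute change in the probability the rule targets


@dataclass
class AdjustmentLedger:
    """Audit trail of the adjustment step.

    ``original`` is the raw FRAX output, ``baseline`` the glucocorticoid
    re-baselined value, ``final`` the value after applying the single
    dominant refinement (if any).  ``candidates`` records every applicable
    rule, applied or not; ``notes`` carries the non-numeric flags (recent
    MOF, very-high-dose glucocorticoids, caveats).
    """

    original: FraxProbabilities
    baseline: FraxProbabilities
    final: FraxProbabilities
    gc_tier: GlucocorticoidTier = GlucocorticoidTier.NONE
    candidates: list[AdjustmentCandidate] = field(default_factory=list)
    applied: str | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "original": {"mof_pct": self.original.mof_pct, "hip_pct": self.original.hip_pct},
            "gc_tier": self.gc_tier.value,
            "baseline": {"mof_pct": self.baseline.mof_pct, "hip_pct": self.baseline.hip_pct},
            "candidates": [
                {
                    "rule": c.name,
                    "mof_pct": c.adjusted.mof_pct,
                    "hip_pct": c.adjusted.hip_pct,
                    "delta": c.delta,
                }
                for c in self.candidates
            ],
            "applied": self.applied,
            "final": {"mof_pct": self.final.mof_pct, "hip_pct": self.final.hip_pct},
            "notes": list(self.notes),
        }


def select_dominant(probs: FraxProbabilities, profile: "PatientProfile") -> AdjustmentLedger:
    """Apply the glucocorticoid re-baseline, then the single dominant refinement.

    Every applicable refinement (falls, spine discordance, TBS, HAL) is
    evaluated independently on the glucocorticoid-adjusted probabilities;
    the one producing the largest absolute change in its own target
    probability is applied (the falls rule targets both outcomes and is
    scored by the larger of its two changes; ties go to the earlier rule in
    that fixed order).  All candidates and non-numeric flags are recorded.
    """
    tier = GlucocorticoidTier(getattr(profile, "gc_dose_tier", "none"))
    baseline = adjust_glucocorticoid(probs, tier)
    ledger = AdjustmentLedger(original=probs, baseline=baseline, final=baseline, gc_tier=tier)

    if tier is GlucocorticoidTier.VERY_HIGH:
        ledger.notes.append(
            "very-high-dose glucocorticoids (> 20 mg/day prednisolone-equivalent): "
            "greater upward adjustment of fracture probability is required; "
            "high-dose multipliers applied"
        )
    recent = getattr(profile, "recent_mof_months", None)
    if recent is not None and recent <= 24:
        ledger.notes.append(
            "recent major osteoporotic fracture: marked (unquantified) uplift to "
            "fracture probabilities applies; flag only, no numeric change"
        )
    if str(getattr(getattr(profile, "diabetes", "none"), "value", getattr(profile, "diabetes", "none"))) == "type1":
        ledger.notes.append(
            "type 1 diabetes: no empirical post-FRAX adjustment; handled as for "
            "type 2 via the rheumatoid-arthritis FRAX input"
        )

    candidates: list[AdjustmentCandidate] = []

    if getattr(profile, "recurrent_falls", False):
        adj = adjust_falls(baseline, True)
        delta = max(abs(adj.mof_pct - baseline.mof_pct), abs(adj.hip_pct - baseline.hip_pct))
        candidates.append(AdjustmentCandidate("falls", adj, delta))

    ls = getattr(profile, "ls_tscore", None)
    fn = getattr(profile, "fn_tscore", None)
    if ls is not None and fn is not None and probs.bmd_included:
        d = int(round_half_away(fn - ls))
        if d < 0 and not getattr(profile, "reliable_high_spine_bmd", False):
            ledger.notes.append(
                "discordantly high spine BMD: downward adjustment withheld without "
                "a reliable spine measurement (possible degenerative artefact)"
            )
        elif d != 0:
            adj = adjust_spine_discordance(
                baseline, ls, fn, getattr(profile, "reliable_high_spine_bmd", False)
            )
            candidates.append(
                AdjustmentCandidate(
                    "spine_discordance", adj, abs(adj.mof_pct - baseline.mof_pct)
                )
            )

    tbs = getattr(profile, "tbs_sd_decrease", None)
    if tbs is not None and tbs != 0:
        adj = adjust_tbs(baseline, tbs)
        candidates.append(AdjustmentCandidate("tbs", adj, abs(adj.mof_pct - baseline.mof_pct)))

    hal = getattr(profile, "hal_sd_diff", None)
    if hal is not None and hal != 0:
        adj = adjust_hal(baseline, hal)
        candidates.append(AdjustmentCandidate("hal", adj, abs(adj.hip_pct - baseline.hip_pct)))

    ledger.candidates = candidates
    if candidates:
        best = max(candidates, key=lambda c: c.delta)  # max() keeps the first on ties
        ledger.applied = best.name
        ledger.final = best.adjusted
        if best.name == "falls":
            ledger.notes.append(
                "recurrent falls: drug treatment affecting bone metabolism alone "
                "may not fully address falls-related fracture risk; falls "
                "assessment advised"
            )
    return ledger
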