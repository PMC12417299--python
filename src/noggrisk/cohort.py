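"""Reproducible synthetic patient cohorts for pipeline testing.

The guideline publishes no cohort-level input distributions, so this
generator makes explicitly synthetic choices: a mostly-female assessment
population aged 50-90, a log-normal 10-year MOF probability whose median
rises with age (positivity and right skew are the only claims made), a hip
probability that is a noisy fraction of the MOF probability, and
independently drawn risk-factor flags at configurable prevalences with
configurable missingness.  No epidemiological calibration is claimed; every
parameter can be overridden through :class:`CohortConfig`.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .categorise import Category, RiskAssessment
from .io import PatientRecord

__all__ = ["CohortConfig", "generate_cohort", "cohort_summary"]


class CohortConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    ``mof_median_at_50`` / ``mof_median_at_90`` set the age trend of the
    log-normal MOF probability (percent scale); ``mof_log_sigma`` its
    spread on the log scale.  ``hip_fraction_of_mof`` is the central
    hip/MOF ratio, jittered per patient.  Prevalences and missingness are
    per-field probabilities in [0, 1].
    """

    n: int = Field(default=1000, ge=0)
    seed: int = 0
    age_range: tuple[float, float] = (50.0, 90.0)
    sex_mix: float = Field(default=0.75, ge=0, le=1)  # proportion female
    mof_median_at_50: float = Field(default=5.0, gt=0)
    mof_median_at_90: float = Field(default=30.0, gt=0)
    mof_log_sigma: float = Field(default=0.55, gt=0)
    hip_fraction_of_mof: float = Field(default=0.25, gt=0, le=1)
    hip_fraction_log_sigma: float = Field(default=0.45, gt=0)
    bmd_included_prob: float = Field(default=0.5, ge=0, le=1)
    risk_factor_prevalences: dict[str, float] = Field(
        default_factory=lambda: {
            "recurrent_falls": 0.15,
            "parkinsons": 0.02,
            "prior_fragility_fracture": 0.25,
            "kyphosis": 0.05,
            "acute_back_pain": 0.05,
            "recent_mof": 0.08,
            "vertebral_fracture": 0.10,
            "diabetes_type2": 0.10,
            "diabetes_type1": 0.01,
            "gc_any": 0.08,
        }
    )
    missingness: dict[str, float] = Field(
        default_factory=lambda: {
            "ls_tscore": 0.5,
            "fn_tscore": 0.5,
            "tbs_sd_decrease": 0.8,
            "hal_sd_diff": 0.8,
            "height_loss_cm": 0.6,
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        lo, hi = self.age_range
        if not (lo < hi and lo >= 45):
            raise ValueError("age_range must satisfy 45 <= low < high")
        for name, probs in (
            ("risk_factor_prevalences", self.risk_factor_prevalences),
            ("missingness", self.missingness),
        ):
            for key, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{key}] = {p} outside [0, 1]")
        return self


def _mof_median(age: float, cfg: CohortConfig) -> float:
    """Log-linear interpolation of the median MOF probability in age."""
    t = (age - 50.0) / 40.0
    return math.exp(
        (1 - t) * math.log(cfg.mof_median_at_50) + t * math.log(cfg.mof_median_at_90)
    )


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate ``config.n`` synthetic patient records.

    Deterministic for a fixed config (identical seed and parameters give a
    bit-identical cohort); probabilities always land strictly inside
    (0, 100).
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    prev = cfg.risk_factor_prevalences
    miss = cfg.missingness
    records: list[PatientRecord] = []
    for i in range(cfg.n):
        age = float(rng.uniform(*cfg.age_range))
        sex = "female" if rng.random() < cfg.sex_mix else "male"
        mof = float(
            np.clip(
                _mof_median(age, cfg) * math.exp(rng.normal(0.0, cfg.mof_log_sigma)),
                0.01, 99.9,
            )
        )
        frac = cfg.hip_fraction_of_mof * math.exp(rng.normal(0.0, cfg.hip_fraction_log_sigma))
        hip = float(np.clip(mof * min(frac, 1.0), 0.01, 99.9))

        def present(field: str) -> bool:
            return rng.random() >= miss.get(field, 0.0)

        bmd_included = bool(rng.random() < cfg.bmd_included_prob)
        ls = float(rng.normal(-1.5, 1.2)) if (bmd_included and present("ls_tscore")) else None
        fn = float(rng.normal(-1.5, 1.0)) if (bmd_included and present("fn_tscore")) else None
        tbs = float(rng.normal(0.5, 0.8)) if present("tbs_sd_decrease") else None
        hal = float(rng.normal(0.0, 1.0)) if present("hal_sd_diff") else None
        height_loss = float(abs(rng.normal(1.0, 2.0))) if present("height_loss_cm") else None

        gc_tier = "none"
        if rng.random() < prev.get("gc_any", 0.0):
            gc_tier = str(rng.choice(["low", "medium", "high", "very_high"],
                                     p=[0.2, 0.45, 0.3, 0.05]))
        diabetes = "none"
        r = rng.random()
        if r < prev.get("diabetes_type1", 0.0):
            diabetes = "type1"
        elif r < prev.get("diabetes_type1", 0.0) + prev.get("diabetes_type2", 0.0):
            diabetes = "type2"

        vf_count = 0
        recent_vf = False
        if rng.random() < prev.get("vertebral_fracture", 0.0):
            vf_count = int(rng.integers(1, 4))
            recent_vf = bool(rng.random() < 0.3)
        recent_mof = (
            float(rng.uniform(0, 24)) if rng.random() < prev.get("recent_mof", 0.0) else None
        )
        prior_fx = bool(rng.random() < prev.get("prior_fragility_fracture", 0.0))
        if recent_mof is not None or vf_count > 0:
            prior_fx = True

        records.append(
            PatientRecord(
                record_id=f"P{i:05d}",
                age=age,
                sex=sex,
                mof_pct=mof,
                hip_pct=hip,
                bmd_included=bmd_included,
                gc_dose_tier=gc_tier,
                ls_tscore=ls,
                fn_tscore=fn,
                tbs_sd_decrease=tbs,
                hal_sd_diff=hal,
                recurrent_falls=bool(rng.random() < prev.get("recurrent_falls", 0.0)),
                diabetes=diabetes,
                parkinsons=bool(rng.random() < prev.get("parkinsons", 0.0)),
                prior_fragility_fracture=prior_fx,
                recent_mof_months=recent_mof,
                vertebral_fracture_count=vf_count,
                recent_vertebral_fracture=recent_vf,
                height_loss_cm=height_loss,
                kyphosis=bool(rng.random() < prev.get("kyphosis", 0.0)),
                acute_back_pain=bool(rng.random() < prev.get("acute_back_pain", 0.0)),
            )
        )
    return records


def cohort_summary(assessments: list[RiskAssessment]) -> dict:
    """Category proportions and action counts over a batch of assessments."""
    n = len(assessments)
    cat_counts = Counter(a.overall_category.token for a in assessments)
    action_counts = Counter(a.action.value for a in assessments)
    proportions = {c.token: cat_counts.get(c.token, 0) / n if n else 0.0 for c in Category}
    return {
        "n": n,
        "category_counts": dict(cat_counts),
        "category_proportions": proportions,
        "action_counts": dict(action_counts),
    }
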