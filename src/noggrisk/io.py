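"""Batch input/output and guideline-conformant patient-facing text.

Reads per-patient records from CSV or JSON-lines, validates each row
(collecting per-row errors rather than aborting the batch), writes
assessments back out with a JSON audit ledger per row, and renders the
numeric risk-communication sentence and lifestyle-advice constants the
guideline specifies.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .adjustments import FraxProbabilities, GlucocorticoidTier, Sex, round_half_away
from .categorise import Diabetes, PatientProfile, RiskAssessment

__all__ = [
    "FileFormat",
    "PatientRecord",
    "RowError",
    "ReadResult",
    "AssessedPatient",
    "read_patients",
    "write_assessments",
    "read_assessments",
    "frequency_statement",
    "lifestyle_advice",
]


class FileFormat(str, enum.Enum):
    CSV = "csv"
    JSON = "json"  # JSON-lines: one record object per line


class PatientRecord(BaseModel):
    """One input row: identifier, FRAX probabilities and risk-factor flags.

    All risk-factor fields are optional; a missing value is an explicit
    null and is never interpreted as risk-factor-present.
    """

    record_id: str
    age: float = Field(gt=0)
    sex: Sex = Sex.FEMALE
    mof_pct: float = Field(ge=0, le=100)
    hip_pct: float = Field(ge=0, le=100)
    bmd_included: bool = False
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

    def to_profile(self) -> PatientProfile:
        data = self.model_dump(exclude={"record_id", "mof_pct", "hip_pct", "bmd_included"})
        return PatientProfile(**data)

    def to_probabilities(self) -> FraxProbabilities:
        return FraxProbabilities(
            mof_pct=self.mof_pct,
            hip_pct=self.hip_pct,
            bmd_included=self.bmd_included,
            age=self.age,
            sex=self.sex,
        )


@dataclass
class RowError:
    row: int  # zero-based data-row index
    record_id: str | None
    message: str


@dataclass
class ReadResult:
    records: list[PatientRecord]
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _infer_format(path: str | Path, fmt: FileFormat | str | None) -> FileFormat:
    if fmt is not None:
        return FileFormat(fmt)
    suffix = Path(path).suffix.lower()
    return FileFormat.JSON if suffix in (".json", ".jsonl", ".ndjson") else FileFormat.CSV


def _row_dicts(path: Path, fmt: FileFormat) -> list[dict]:
    if fmt is FileFormat.CSV:
        df = pd.read_csv(path, dtype=object, keep_default_na=True)
        return [
            {k: (None if (isinstance(v, float) and math.isnan(v)) or v is None else v)
             for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]
    rows = []
    text = path.read_text()
    stripped = text.strip()
    if stripped.startswith("["):  # also accept a plain JSON array
        rows = json.loads(stripped)
    else:
        for line in stripped.splitlines():
            if line.strip():
                rows.append(json.loads(line))
    return rows


def read_patients(
    path: str | Path, format: FileFormat | str | None = None
) -> ReadResult:
    """Read and validate a batch of patient records.

    A malformed file raises; an invalid row is recorded in ``errors`` and
    skipped.  Duplicate ``record_id`` values are rejected (later duplicates
    are skipped).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    raw = _row_dicts(path, fmt)
    result = ReadResult(records=[])
    seen: set[str] = set()
    for i, row in enumerate(raw):
        rid = row.get("record_id")
        try:
            # explicit nulls fall back to the documented absent/false defaults
            rec = PatientRecord(**{k: v for k, v in row.items() if v is not None})
        except ValidationError as exc:
            result.errors.append(RowError(i, str(rid) if rid is not None else None, str(exc)))
            continue
        if rec.record_id in seen:
            result.errors.append(
                RowError(i, rec.record_id, f"duplicate record_id {rec.record_id!r}")
            )
            continue
        seen.add(rec.record_id)
        result.records.append(rec)
    return result


@dataclass
class AssessedPatient:
    """A record paired with its assessment, ready for serialisation."""

    record: PatientRecord
    assessment: RiskAssessment

    def to_row(self) -> dict:
        a = self.assessment.to_dict()
        ledger = a["ledger"] or {}
        final = ledger.get("final", {})
        return {
            "record_id": self.record.record_id,
            "age": self.record.age,
            "sex": self.record.sex.value,
            "mof_pct": self.record.mof_pct,
            "hip_pct": self.record.hip_pct,
            "adjusted_mof_pct": final.get("mof_pct"),
            "adjusted_hip_pct": final.get("hip_pct"),
            "applied_adjustment": ledger.get("applied"),
            "mof_category": a["mof_category"],
            "hip_category": a["hip_category"],
            "overall_category": a["overall_category"],
            "action": a["action"],
            "vfa_indicated": a["vfa_indicated"],
            "referral_reasons": json.dumps(a["referral_reasons"]),
            "notes": json.dumps(a["notes"]),
            "ledger": json.dumps(ledger, sort_keys=True),
            "dual_points": json.dumps(a["dual_points"], sort_keys=True),
        }


#: Deterministic output column order.
ASSESSMENT_COLUMNS = [
    "record_id", "age", "sex", "mof_pct", "hip_pct",
    "adjusted_mof_pct", "adjusted_hip_pct", "applied_adjustment",
    "mof_category", "hip_category", "overall_category", "action",
    "vfa_indicated", "referral_reasons", "notes", "ledger", "dual_points",
]


def write_assessments(
    assessed: list[AssessedPatient],
    path: str | Path,
    format: FileFormat | str | None = None,
) -> None:
    """Write assessments with a fixed column order; byte-identical across runs."""
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = [a.to_row() for a in assessed]
    if fmt is FileFormat.CSV:
        df = pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS)
        df.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps({c: row[c] for c in ASSESSMENT_COLUMNS}) + "\n")


def read_assessments(path: str | Path, format: FileFormat | str | None = None) -> list[dict]:
    """Read back written assessments (JSON columns re-parsed)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt is FileFormat.CSV:
        df = pd.read_csv(path, dtype=object)
        rows = df.to_dict(orient="records")
    else:
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
    for row in rows:
        for col in ("referral_reasons", "notes", "ledger", "dual_points"):
            if isinstance(row.get(col), str):
                row[col] = json.loads(row[col])
    return rows


def frequency_statement(prob_pct: float) -> str:
    """Natural-frequency risk sentence with positive and negative framing.

    A 23% 10-year probability reads: "Of 100 people like you, over the next
    10 years, 23 will break a bone and 77 will not."  Probabilities below
    0.5% render as "fewer than 1 in 100" to avoid a misleading zero.
    """
    if not 0 <= prob_pct <= 100:
        raise ValueError(f"probability must be in [0, 100], got {prob_pct}")
    if 0 < prob_pct < 0.5:
        return (
            "Of 100 people like you, over the next 10 years, fewer than 1 "
            "will break a bone."
        )
    n = int(round_half_away(prob_pct))
    return (
        f"Of 100 people like you, over the next 10 years, {n} will break a "
        f"bone and {100 - n} will not."
    )


def lifestyle_advice() -> list[dict]:
    """The guideline's lifestyle recommendations with their numeric constants."""
    return [
        {
            "item": "calcium",
            "advice": "adequate calcium intake, preferably dietary",
            "minimum": 700, "unit": "mg/day",
        },
        {
            "item": "vitamin_d",
            "advice": "vitamin D supplementation where insufficiency or risk "
                      "factors for it are identified",
            "minimum": 800, "unit": "IU/day",
        },
        {
            "item": "alcohol",
            "advice": "restrict alcohol intake",
            "maximum": 2, "unit": "units/day",
        },
        {
            "item": "exercise",
            "advice": "regular combined weight-bearing and muscle-strengthening "
                      "exercise, tailored to the individual",
        },
        {
            "item": "smoking",
            "advice": "smoking cessation advice for current smokers",
        },
        {
            "item": "falls",
            "advice": "falls assessment, with balance/combined exercise "
                      "programmes for those at risk",
        },
    ]
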