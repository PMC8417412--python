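"""Domain model for neonatal late-onset-sepsis (LOS) work-up cohorts.

A :class:`PatientRecord` holds one infant's raw clinical and laboratory
observations summarised over the work-up window (6 h before the sepsis
work-up until 24 h after, work-up time being t = 0), plus the
culture-confirmed outcome label.  :func:`derive_markers` turns the raw
values into the binary sepsis markers used throughout the analysis
(elevated CRP, elevated NLR, lymphopenia, ...), applying every threshold
as a strict inequality in the stated direction — a value exactly at a
cutoff is normal.

Markers are three-valued: ``True`` / ``False`` / ``None`` (missing).  A
missing laboratory value yields a missing marker, never a silently
negative one; downstream the antibiotic-discontinuation rule treats a
missing CRP/NLR as "cannot rule out" (see :mod:`neolos.rule`).
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Cohort",
    "Sex",
    "HealthScore",
    "PatientRecord",
    "MarkerPanel",
    "MARKER_NAMES",
    "NLR_SENTINEL",
    "CohortValidationError",
    "compute_nlr",
    "derive_markers",
    "kleene_or",
    "read_cohort",
    "write_cohort",
    "panel_frame",
    "outcome_vector",
]

#: Sentinel NLR when the lymphocyte count is zero: the ratio is undefined
#: but exceeds any finite threshold, so it is treated as "high" downstream.
NLR_SENTINEL: float = math.inf


class Cohort(str, enum.Enum):
    DEVELOPMENT = "development"
    VALIDATION = "validation"


class Sex(str, enum.Enum):
    F = "f"
    M = "m"


class HealthScore(str, enum.Enum):
    """Blinded 3-level clinical appearance grade assigned at work-up and 24 h."""

    HEALTHY = "healthy"
    EQUIVOCAL = "equivocal"
    SICK = "sick"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


_SEVERITY = {HealthScore.HEALTHY: 0, HealthScore.EQUIVOCAL: 1, HealthScore.SICK: 2}


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the schema."""


class PatientRecord(BaseModel):
    """One infant's observations over the [-6 h, +24 h] work-up window.

    ``*_min`` / ``*_max`` fields are window extrema.  Laboratory fields are
    optional: a test not drawn is ``None``.  ``time_to_positivity_h`` is the
    real time from blood draw to the laboratory flagging growth and is
    present iff the culture is positive.  LOS is defined by a positive
    blood culture, so ``sepsis`` implies ``culture_positive``.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    cohort: Cohort
    gestational_age_weeks: float
    corrected_ga_weeks: float
    birthweight_g: float
    sex: Sex
    day_of_life: int
    central_line: bool
    parenteral_nutrition: bool
    temp_min_c: Optional[float] = None
    temp_max_c: Optional[float] = None
    hr_max_bpm: Optional[float] = None
    glucose_max_mgdl: Optional[float] = None
    wbc_min: Optional[float] = None
    wbc_max: Optional[float] = None
    anc_min: Optional[float] = None
    anc_max: Optional[float] = None
    lymph_min: Optional[float] = None
    platelets_min: Optional[float] = None
    crp_max_mgdl: Optional[float] = None
    nlr_max: Optional[float] = None
    health_score_0h: HealthScore
    health_score_24h: HealthScore
    culture_positive: bool
    time_to_positivity_h: Optional[float] = None
    sepsis: bool

    @model_validator(mode="after")
    def _check_invariants(self) -> "PatientRecord":
        if not (22.0 <= self.gestational_age_weeks <= 44.0):
            raise ValueError(
                f"gestational_age_weeks must lie in [22, 44], got {self.gestational_age_weeks}"
            )
        if self.day_of_life < 0:
            raise ValueError("day_of_life must be non-negative")
        for name in (
            "birthweight_g", "hr_max_bpm", "glucose_max_mgdl", "wbc_min", "wbc_max",
            "anc_min", "anc_max", "lymph_min", "platelets_min", "crp_max_mgdl",
            "nlr_max", "time_to_positivity_h",
        ):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if (self.time_to_positivity_h is not None) != self.culture_positive:
            raise ValueError(
                "time_to_positivity_h must be present iff culture_positive"
            )
        if self.sepsis and not self.culture_positive:
            raise ValueError(
                "sepsis=true with culture_positive=false: LOS is defined by a "
                "positive blood culture"
            )
        for lo, hi in (("temp_min_c", "temp_max_c"), ("wbc_min", "wbc_max"),
                       ("anc_min", "anc_max")):
            a, b = getattr(self, lo), getattr(self, hi)
            if a is not None and b is not None and a > b:
                raise ValueError(f"{lo} > {hi} ({a} > {b})")
        return self


#: Marker names in panel order; also the column order of `panel_frame`.
MARKER_NAMES: tuple[str, ...] = (
    "crp_high",
    "nlr_high",
    "crp_or_nlr",
    "lymphopenia",
    "abnormal_neutrophils",
    "abnormal_wbc",
    "thrombocytopenia",
    "hyperglycemia",
    "abnormal_temperature",
    "tachycardia",
    "sick_appearing",
    "culture_positive_24h",
)


class MarkerPanel(BaseModel):
    """Derived binary sepsis markers for one infant; ``None`` means missing."""

    model_config = ConfigDict(frozen=True)

    crp_high: Optional[bool]
    nlr_high: Optional[bool]
    crp_or_nlr: Optional[bool]
    lymphopenia: Optional[bool]
    abnormal_neutrophils: Optional[bool]
    abnormal_wbc: Optional[bool]
    thrombocytopenia: Optional[bool]
    hyperglycemia: Optional[bool]
    abnormal_temperature: Optional[bool]
    tachycardia: Optional[bool]
    sick_appearing: bool
    culture_positive_24h: bool

    def as_dict(self) -> dict[str, Optional[bool]]:
        return {name: getattr(self, name) for name in MARKER_NAMES}


def compute_nlr(anc: float, lymphocytes: float) -> float:
    """Neutrophil-to-lymphocyte ratio, ``anc / lymphocytes``.

    A zero lymphocyte count returns :data:`NLR_SENTINEL` (infinity): the
    ratio is undefined but sits above any clinical threshold.
    """
    if anc < 0 or lymphocytes < 0:
        raise ValueError("cell counts must be non-negative")
    if lymphocytes == 0:
        return NLR_SENTINEL
    return anc / lymphocytes


def kleene_or(a: Optional[bool], b: Optional[bool]) -> Optional[bool]:
    """Three-valued OR: True dominates missing; False OR missing is missing."""
    if a is True or b is True:
        return True
    if a is None or b is None:
        return None
    return False


def _gt(value: Optional[float], cutoff: float) -> Optional[bool]:
    return None if value is None else value > cutoff


def _lt(value: Optional[float], cutoff: float) -> Optional[bool]:
    return None if value is None else value < cutoff


def derive_markers(record: PatientRecord) -> MarkerPanel:
    """Apply the marker definitions to one record.

    Cutoffs (all strict): CRP > 0.75 mg/dl; NLR > 1.5; lymphocytes
    < 2,000/mm3; neutrophils < 1,800 or > 5,400/mm3; leukocytes < 5,000 or
    > 20,000/mm3; platelets < 150,000/mm3; glucose > 108 mg/dl; temperature
    < 36 or > 37.5 C; heart rate > 186 bpm.  ``sick_appearing`` is the
    worst-in-window appearance dichotomised sick vs (healthy, equivocal);
    ``culture_positive_24h`` requires time-to-positivity <= 24 h.
    """
    ttp = record.time_to_positivity_h
    return MarkerPanel(
        crp_high=_gt(record.crp_max_mgdl, 0.75),
        nlr_high=_gt(record.nlr_max, 1.5),
        crp_or_nlr=kleene_or(_gt(record.crp_max_mgdl, 0.75), _gt(record.nlr_max, 1.5)),
        lymphopenia=_lt(record.lymph_min, 2000.0),
        abnormal_neutrophils=kleene_or(
            _lt(record.anc_min, 1800.0), _gt(record.anc_max, 5400.0)
        ),
        abnormal_wbc=kleene_or(
            _lt(record.wbc_min, 5000.0), _gt(record.wbc_max, 20000.0)
        ),
        thrombocytopenia=_lt(record.platelets_min, 150000.0),
        hyperglycemia=_gt(record.glucose_max_mgdl, 108.0),
        abnormal_temperature=kleene_or(
            _lt(record.temp_min_c, 36.0), _gt(record.temp_max_c, 37.5)
        ),
        tachycardia=_gt(record.hr_max_bpm, 186.0),
        sick_appearing=(
            record.health_score_0h is HealthScore.SICK
            or record.health_score_24h is HealthScore.SICK
        ),
        culture_positive_24h=bool(record.culture_positive and ttp is not None and ttp <= 24.0),
    )


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

FIELD_ORDER: tuple[str, ...] = tuple(PatientRecord.model_fields)

_BOOL_FIELDS = {
    "central_line", "parenteral_nutrition", "culture_positive", "sepsis",
}
_OPTIONAL_FLOAT_FIELDS = {
    "temp_min_c", "temp_max_c", "hr_max_bpm", "glucose_max_mgdl", "wbc_min",
    "wbc_max", "anc_min", "anc_max", "lymph_min", "platelets_min",
    "crp_max_mgdl", "nlr_max", "time_to_positivity_h",
}


def _encode(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    return str(value)


def _parse_bool(text: str, field: str, row: int) -> bool:
    if text in ("true", "false"):
        return text == "true"
    raise CohortValidationError(
        f"row {row}: field {field!r}: expected 'true' or 'false', got {text!r}"
    )


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write a cohort CSV (one row per infant, header of field names)."""
    rows = [
        {name: _encode(getattr(rec, name)) for name in FIELD_ORDER}
        for rec in records
    ]
    frame = pd.DataFrame(rows, columns=list(FIELD_ORDER))
    frame.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises :class:`CohortValidationError` naming the 1-based data row on
    any unknown column, malformed enum/boolean, negative count, or record
    violating a domain invariant.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    unknown = set(frame.columns) - set(FIELD_ORDER)
    if unknown:
        raise CohortValidationError(f"unknown columns: {sorted(unknown)}")
    missing = set(FIELD_ORDER) - set(frame.columns)
    if missing:
        raise CohortValidationError(f"missing columns: {sorted(missing)}")
    records: list[PatientRecord] = []
    for i, raw in enumerate(frame.to_dict(orient="records"), start=1):
        data: dict = {}
        for name in FIELD_ORDER:
            text = raw[name].strip()
            if name in _OPTIONAL_FLOAT_FIELDS:
                if text == "":
                    data[name] = None
                elif text == "inf":
                    data[name] = math.inf
                else:
                    try:
                        data[name] = float(text)
                    except ValueError:
                        raise CohortValidationError(
                            f"row {i}: field {name!r}: not a number: {text!r}"
                        ) from None
            elif name in _BOOL_FIELDS:
                data[name] = _parse_bool(text, name, i)
            else:
                data[name] = text
        try:
            records.append(PatientRecord(**data))
        except ValueError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from exc
    return records


def panel_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Derive markers for every record into a DataFrame (object dtype,
    values True/False/None), indexed by patient_id in input order."""
    panels = [derive_markers(rec).as_dict() for rec in records]
    frame = pd.DataFrame(panels, columns=list(MARKER_NAMES), dtype=object)
    frame.index = pd.Index([rec.patient_id for rec in records], name="patient_id")
    return frame


def outcome_vector(records: Sequence[PatientRecord]) -> np.ndarray:
    """Boolean outcome labels (True = culture-confirmed LOS) in input order."""
    return np.array([rec.sepsis for rec in records], dtype=bool)
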