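"""Core domain types and delimited-file I/O for longitudinal canine EHRs.

The package represents time as fractional patient age in years; every window
(post-diagnosis grace period, no-CKD look-ahead, eligibility window) is plain
arithmetic on ``age_years``.  Missing values are represented by *absence*: an
analyte a visit did not measure is simply not a key of ``VisitRecord.analytes``
(and an empty field in the on-disk long format).  Zero is never a missing
sentinel.

The on-disk long format is UTF-8 CSV with a header row and columns::

    patient_id, sex, breed, age_years, weight_kg, analyte, value,
    note_tokens, diagnosis_codes

one row per patient-visit-analyte (demographics repeated; ``note_tokens`` and
``diagnosis_codes`` are ``|``-separated).  A visit with no analyte values is
written as a single row with empty ``analyte``/``value`` fields.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "BLOOD",
    "URINE",
    "AGE_MIN_YEARS",
    "AGE_MAX_YEARS",
    "DAYS_30_YEARS",
    "AnalyteInfo",
    "AnalyteCatalog",
    "VisitRecord",
    "PatientRecord",
    "CKDStatus",
    "LabeledRecord",
    "SchemaError",
    "ParseError",
    "ConfigurationError",
    "default_catalog",
    "read_ehr_table",
    "write_ehr_table",
    "validate_record",
    "visit_has_category",
]

BLOOD = "blood"
URINE = "urine"

#: cohort age bounds (years): puppies below 1.5 y and implausible ages are out.
AGE_MIN_YEARS = 1.5
AGE_MAX_YEARS = 22.0

#: 30 calendar days expressed as fractional years.
DAYS_30_YEARS = 30.0 / 365.25

EHR_COLUMNS = (
    "patient_id",
    "sex",
    "breed",
    "age_years",
    "weight_kg",
    "analyte",
    "value",
    "note_tokens",
    "diagnosis_codes",
)


class SchemaError(ValueError):
    """A file or record violates the documented schema (e.g. unknown analyte)."""


class ParseError(ValueError):
    """A delimited file row could not be parsed; the message names the line."""


class ConfigurationError(ValueError):
    """A configuration object is inconsistent with the data it is applied to."""


@dataclass(frozen=True)
class AnalyteInfo:
    """Units, canine reference interval and specimen category of one analyte."""

    units: str
    normal_low: float
    normal_high: float
    category: str  # BLOOD or URINE

    def __post_init__(self) -> None:
        if not self.normal_low < self.normal_high:
            raise ValueError(
                f"normal_low must be < normal_high, got [{self.normal_low}, {self.normal_high}]"
            )
        if self.category not in (BLOOD, URINE):
            raise ValueError(f"category must be '{BLOOD}' or '{URINE}', got {self.category!r}")


@dataclass(frozen=True)
class AnalyteCatalog:
    """Per-analyte units, normal ranges and blood/urine category.

    Drives outlier masking and the CKD-suggesting flags used by labeling.
    The default catalog (``default_catalog()``) ships 35 analytes; creatinine,
    BUN, USG and urine_protein are mandatory in any catalog.
    """

    entries: dict[str, AnalyteInfo]

    MANDATORY = ("creatinine", "BUN", "USG", "urine_protein")

    def __post_init__(self) -> None:
        missing = [a for a in self.MANDATORY if a not in self.entries]
        if missing:
            raise ValueError(f"catalog is missing mandatory analytes: {missing}")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> AnalyteInfo:
        return self.entries[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def names_in_category(self, category: str) -> tuple[str, ...]:
        return tuple(n for n, info in self.entries.items() if info.category == category)

    @property
    def blood_names(self) -> tuple[str, ...]:
        return self.names_in_category(BLOOD)

    @property
    def urine_names(self) -> tuple[str, ...]:
        return self.names_in_category(URINE)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalyteCatalog":
        entries = {
            str(name): AnalyteInfo(
                units=str(spec["units"]),
                normal_low=float(spec["normal_low"]),
                normal_high=float(spec["normal_high"]),
                category=str(spec["category"]),
            )
            for name, spec in mapping.items()
        }
        return cls(entries=entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalyteCatalog":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_catalog() -> AnalyteCatalog:
    """The packaged 35-analyte canine catalog."""
    text = resources.files("ckdpipe.data").joinpath("analyte_catalog.yaml").read_text("utf-8")
    return AnalyteCatalog.from_mapping(yaml.safe_load(text))


@dataclass
class VisitRecord:
    """One clinic visit: age, optional weight, analyte values, notes, diagnoses."""

    age_years: float
    weight_kg: float | None = None
    analytes: dict[str, float] = field(default_factory=dict)
    note_tokens: set[str] = field(default_factory=set)
    diagnosis_codes: set[str] = field(default_factory=set)


@dataclass
class PatientRecord:
    """One animal: demographics plus its age-ordered visit sequence."""

    patient_id: str
    sex: str  # "male" | "female"
    breed: str
    visits: list[VisitRecord] = field(default_factory=list)


class CKDStatus(str, Enum):
    CKD = "CKD"
    PROBABLE_CKD = "PROBABLE_CKD"
    NO_CKD = "NO_CKD"
    EXCLUDED = "EXCLUDED"


@dataclass
class LabeledRecord:
    """A PatientRecord with assigned CKD status, evaluation age T0 and the
    visit subset usable for modelling.

    ``t0_years`` is present iff status is CKD or NO_CKD.  ``provenance`` marks
    truncation-augmented copies as ``(origin patient_id, k visits removed)``.
    """

    patient: PatientRecord
    status: CKDStatus
    t0_years: float | None
    usable_visits: list[VisitRecord]
    provenance: tuple[str, int] | None = None

    @property
    def patient_id(self) -> str:
        return self.patient.patient_id


def visit_has_category(visit: VisitRecord, catalog: AnalyteCatalog, category: str) -> bool:
    """True if the visit has at least one observed analyte of the category."""
    return any(
        name in catalog and catalog[name].category == category for name in visit.analytes
    )


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        v = float(text)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: cannot parse {what} {text!r} as a number") from exc
    if math.isnan(v):
        raise ParseError(f"line {lineno}: NaN is not a valid {what}; use an empty field")
    return v


def read_ehr_table(path: str | Path, catalog: AnalyteCatalog) -> list[PatientRecord]:
    """Read the EHR long format into one PatientRecord per distinct patient.

    Visits are returned sorted by ascending age regardless of row order.
    Unknown analyte names raise :class:`SchemaError`; malformed rows raise
    :class:`ParseError` naming the line number.
    """
    patients: dict[str, PatientRecord] = {}
    visits: dict[tuple[str, float], VisitRecord] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != EHR_COLUMNS:
            raise SchemaError(
                f"unexpected header {reader.fieldnames!r}; expected {list(EHR_COLUMNS)}"
            )
        for row in reader:
            lineno = reader.line_num
            if row.get(None) or any(v is None for v in row.values()):
                raise ParseError(f"line {lineno}: wrong number of fields")
            pid = row["patient_id"]
            if not pid:
                raise ParseError(f"line {lineno}: empty patient_id")
            age = _parse_float(row["age_years"], "age_years", lineno)
            if pid not in patients:
                patients[pid] = PatientRecord(
                    patient_id=pid, sex=row["sex"], breed=row["breed"], visits=[]
                )
            key = (pid, age)
            if key not in visits:
                weight = (
                    _parse_float(row["weight_kg"], "weight_kg", lineno)
                    if row["weight_kg"] != ""
                    else None
                )
                visits[key] = VisitRecord(age_years=age, weight_kg=weight)
                patients[pid].visits.append(visits[key])
            visit = visits[key]
            if row["note_tokens"]:
                visit.note_tokens.update(t for t in row["note_tokens"].split("|") if t)
            if row["diagnosis_codes"]:
                visit.diagnosis_codes.update(
                    c for c in row["diagnosis_codes"].split("|") if c
                )
            analyte = row["analyte"]
            if analyte == "":
                continue
            if analyte not in catalog:
                raise SchemaError(f"line {lineno}: unknown analyte {analyte!r}")
            if row["value"] == "":
                continue  # analyte named but value missing: treated as unmeasured
            visit.analytes[analyte] = _parse_float(row["value"], "value", lineno)
    records = list(patients.values())
    for rec in records:
        rec.visits.sort(key=lambda v: v.age_years)
    return records


def write_ehr_table(records: Sequence[PatientRecord], path: str | Path) -> Path:
    """Write records in the EHR long format; inverse of :func:`read_ehr_table`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EHR_COLUMNS)
        for rec in records:
            for visit in rec.visits:
                base = [
                    rec.patient_id,
                    rec.sex,
                    rec.breed,
                    repr(float(visit.age_years)),
                    "" if visit.weight_kg is None else repr(float(visit.weight_kg)),
                ]
                tail = [
                    "|".join(sorted(visit.note_tokens)),
                    "|".join(sorted(visit.diagnosis_codes)),
                ]
                if visit.analytes:
                    for name in sorted(visit.analytes):
                        writer.writerow(base + [name, repr(float(visit.analytes[name]))] + tail)
                else:
                    writer.writerow(base + ["", ""] + tail)
    return path


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_record(record: PatientRecord, catalog: AnalyteCatalog) -> list[str]:
    """Return invariant violations as messages (empty list == valid).

    Value *plausibility* is deliberately not checked here: implausible values
    are handled by outlier masking, not validation.
    """
    violations: list[str] = []
    if not record.visits:
        violations.append("record has no visits")
    if record.sex not in ("male", "female"):
        violations.append(f"sex must be 'male' or 'female', got {record.sex!r}")
    ages = [v.age_years for v in record.visits]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        if len(set(ages)) < len(ages):
            violations.append("duplicate visit ages")
        else:
            violations.append("visits not sorted by ascending age")
    elif len(set(ages)) < len(ages):  # pragma: no cover - subsumed above
        violations.append("duplicate visit ages")
    for v in record.visits:
        if not (AGE_MIN_YEARS <= v.age_years <= AGE_MAX_YEARS):
            violations.append(
                f"visit age {v.age_years} outside [{AGE_MIN_YEARS}, {AGE_MAX_YEARS}]"
            )
        unknown = [a for a in v.analytes if a not in catalog]
        if unknown:
            violations.append(f"visit at age {v.age_years}: unknown analytes {unknown}")
        if v.weight_kg is not None and v.weight_kg <= 0:
            violations.append(f"visit at age {v.age_years}: non-positive weight")
    return violations
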