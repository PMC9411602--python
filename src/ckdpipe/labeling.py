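"""Rule-based CKD status assignment and evaluation-age (T0) anchoring.

Each patient is assigned exactly one of four statuses:

* ``CKD`` — a formal CKD diagnosis code is present.  T0 is the age at the
  first diagnosed visit; visits more than 30 days after diagnosis are trimmed
  from the usable set (a short grace window keeps lab results entered shortly
  after the diagnosis visit).
* ``PROBABLE_CKD`` — no diagnosis, but a CKD-risk note token, or at least two
  CKD-suggesting signals (creatinine above normal, USG below normal, or a
  medical-note phrase from the probable-CKD lexicon).  These records carry no
  T0 and are never used for training or headline metrics.
* ``NO_CKD`` — none of the above and at least two years of recorded history:
  T0 is set two years before the last visit and those last two years are
  removed, validating the absence of a later diagnosis.
* ``EXCLUDED`` — insufficient information for any of the above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .ehr_core import (
    AnalyteCatalog,
    CKDStatus,
    ConfigurationError,
    DAYS_30_YEARS,
    LabeledRecord,
    PatientRecord,
)
from .synth_ehr import PROBABLE_CKD_LEXICON

__all__ = ["LabelingRules", "count_ckd_suggesting_points", "assign_status", "label_cohort"]

_EPS = 1e-9


@dataclass
class LabelingRules:
    """Configuration of the status-assignment rules.

    ``count_mode`` selects how "at least two CKD-suggesting data points" is
    read: ``"distinct_criteria"`` (default) counts each criterion at most
    once; ``"measurements"`` counts every qualifying measurement or token.
    """

    diagnosis_codes_ckd: set[str] = field(default_factory=lambda: {"CKD"})
    probable_note_tokens: set[str] = field(
        default_factory=lambda: set(PROBABLE_CKD_LEXICON)
    )
    risk_note_tokens: set[str] = field(default_factory=lambda: {"CKD_RISK"})
    post_diagnosis_window_years: float = DAYS_30_YEARS
    nockd_lookahead_years: float = 2.0
    min_suggesting_points: int = 2
    count_mode: str = "distinct_criteria"

    def __post_init__(self) -> None:
        if self.post_diagnosis_window_years <= 0 or self.nockd_lookahead_years <= 0:
            raise ValueError("windows must be > 0")
        if self.min_suggesting_points < 1:
            raise ValueError("min_suggesting_points must be >= 1")
        if self.count_mode not in ("distinct_criteria", "measurements"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


def _lower(strings: set[str]) -> set[str]:
    return {s.lower() for s in strings}


def count_ckd_suggesting_points(
    record: PatientRecord, catalog: AnalyteCatalog, rules: LabelingRules
) -> int:
    """Count CKD-suggesting signals anywhere in the record.

    Signals: (a) creatinine above the catalog normal range, (b) USG below it,
    (c) a medical-note token matching the probable-CKD lexicon
    (case-insensitive exact token match).  Under the default
    ``distinct_criteria`` mode each of (a)-(c) counts at most once.
    """
    for analyte in ("creatinine", "USG"):
        if analyte not in catalog:
            raise ConfigurationError(f"catalog lacks {analyte!r}, required for labeling")
    cr_high = catalog["creatinine"].normal_high
    usg_low = catalog["USG"].normal_low
    lexicon = _lower(rules.probable_note_tokens)

    n_high_cr = n_low_usg = n_tokens = 0
    for visit in record.visits:
        cr = visit.analytes.get("creatinine")
        if cr is not None and cr > cr_high:
            n_high_cr += 1
        usg = visit.analytes.get("USG")
        if usg is not None and usg < usg_low:
            n_low_usg += 1
        n_tokens += sum(t.lower() in lexicon for t in visit.note_tokens)
    if rules.count_mode == "measurements":
        return n_high_cr + n_low_usg + n_tokens
    return int(n_high_cr > 0) + int(n_low_usg > 0) + int(n_tokens > 0)


def assign_status(
    record: PatientRecord, catalog: AnalyteCatalog, rules: LabelingRules
) -> LabeledRecord:
    """Assign CKD status, T0 and the usable visit subset to one patient."""
    codes = _lower(rules.diagnosis_codes_ckd)
    diagnosed = [
        v for v in record.visits if _lower(v.diagnosis_codes) & codes
    ]
    if diagnosed:
        t0 = diagnosed[0].age_years  # first diagnosed visit; diagnoses may repeat
        usable = [
            v
            for v in record.visits
            if v.age_years <= t0 + rules.post_diagnosis_window_years + _EPS
        ]
        return LabeledRecord(record, CKDStatus.CKD, t0, usable)

    risk = _lower(rules.risk_note_tokens)
    has_risk = any(_lower(v.note_tokens) & risk for v in record.visits)
    if has_risk or count_ckd_suggesting_points(record, catalog, rules) >= rules.min_suggesting_points:
        return LabeledRecord(record, CKDStatus.PROBABLE_CKD, None, list(record.visits))

    span = record.visits[-1].age_years - record.visits[0].age_years
    if span >= rules.nockd_lookahead_years - _EPS:
        t0 = record.visits[-1].age_years - rules.nockd_lookahead_years
        usable = [v for v in record.visits if v.age_years <= t0 + _EPS]
        return LabeledRecord(record, CKDStatus.NO_CKD, t0, usable)

    return LabeledRecord(record, CKDStatus.EXCLUDED, None, list(record.visits))


def label_cohort(
    records: Sequence[PatientRecord], catalog: AnalyteCatalog, rules: LabelingRules
) -> list[LabeledRecord]:
    """Apply :func:`assign_status` to every record, preserving order."""
    return [assign_status(r, catalog, rules) for r in records]
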