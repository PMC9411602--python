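"""Cohort construction: outlier masking, eligibility filtering, train/test
splitting and truncation augmentation.

Truncation augmentation adds, for every training record with *n* usable
visits, copies with the last *k* visits removed (k = 1..n-1), keeping only
copies whose gap between the new last visit and T0 is at most two years.
This enriches training with records that stop well before diagnosis, which is
what teaches the classifier to recognise the pre-diagnostic trajectory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ehr_core import (
    BLOOD,
    URINE,
    AnalyteCatalog,
    CKDStatus,
    ConfigurationError,
    LabeledRecord,
    visit_has_category,
)

__all__ = [
    "FilterConfig",
    "SplitConfig",
    "AugmentConfig",
    "compute_population_sd",
    "mask_outliers",
    "drop_lab_free_visits",
    "filter_eligible",
    "split_train_test",
    "augment_truncations",
]

logger = logging.getLogger(__name__)
_EPS = 1e-9


@dataclass
class FilterConfig:
    """Outlier rule and eligibility thresholds.

    Fractions are strict inequalities ("more than 50% blood and more than 25%
    urine results" among in-window visits); the visit count is ">=".
    """

    outlier_sd_multiple: float = 6.0
    window_years: float = 4.0
    min_visits_in_window: int = 2
    min_blood_fraction: float = 0.5
    min_urine_fraction: float = 0.25

    def __post_init__(self) -> None:
        if min(self.outlier_sd_multiple, self.window_years, self.min_visits_in_window) <= 0:
            raise ValueError("all thresholds must be positive")
        for frac in (self.min_blood_fraction, self.min_urine_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("fractions must lie in (0, 1)")


@dataclass
class SplitConfig:
    train_fraction: float = 0.67
    seed: int = 0
    stratify_by_status: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class AugmentConfig:
    max_gap_years: float = 2.0
    apply_to: set[CKDStatus] = field(
        default_factory=lambda: {CKDStatus.CKD, CKDStatus.NO_CKD}
    )
    drop_long_gaps: bool = True  # False: keep every truncation regardless of gap

    def __post_init__(self) -> None:
        if self.max_gap_years <= 0:
            raise ValueError("max_gap_years must be > 0")


def compute_population_sd(
    records: Sequence[LabeledRecord], catalog: AnalyteCatalog
) -> dict[str, float]:
    """Observed per-analyte SD across all usable visits of the cohort.

    Analytes with fewer than two observations get SD 0 (the outlier rule then
    reduces to the plain normal-range ceiling for them).
    """
    values: dict[str, list[float]] = {name: [] for name in catalog.names}
    for rec in records:
        for visit in rec.usable_visits:
            for name, v in visit.analytes.items():
                if name in values:
                    values[name].append(v)
    return {
        name: (float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        for name, vals in values.items()
    }


def mask_outliers(
    records: Sequence[LabeledRecord],
    catalog: AnalyteCatalog,
    population_sd: dict[str, float],
    cfg: FilterConfig,
) -> list[LabeledRecord]:
    """Set extreme lab values to missing.

    A value is masked iff it exceeds ``normal_high + outlier_sd_multiple * SD``
    for its analyte.  Only values above the range are masked (low extremes are
    clinically meaningful for e.g. USG).  Returns new records; inputs are not
    mutated.  The number of masked cells is logged.
    """
    out: list[LabeledRecord] = []
    n_masked = 0
    for rec in records:
        new_visits = []
        for visit in rec.usable_visits:
            kept = {}
            for name, v in visit.analytes.items():
                if name not in population_sd:
                    raise ConfigurationError(f"no population SD for analyte {name!r}")
                threshold = catalog[name].normal_high + cfg.outlier_sd_multiple * population_sd[name]
                if v > threshold:
                    n_masked += 1
                else:
                    kept[name] = v
            new_visits.append(replace(visit, analytes=kept,
                                      note_tokens=set(visit.note_tokens),
                                      diagnosis_codes=set(visit.diagnosis_codes)))
        out.append(replace(rec, usable_visits=new_visits))
    logger.info("mask_outliers: masked %d extreme values", n_masked)
    return out


def drop_lab_free_visits(
    record: LabeledRecord,
    catalog: AnalyteCatalog,
    require_both: bool = False,
) -> LabeledRecord:
    """Remove pre-T0 visits without laboratory results.

    Default reading: a visit is dropped if it has *neither* blood nor urine
    values ("lab-free").  ``require_both=True`` switches to the stricter
    conjunctive reading (drop unless both categories are present).  Visits at
    or after T0 are always retained.
    """
    if record.t0_years is None:
        raise ValueError("drop_lab_free_visits requires a record with T0")
    kept = []
    for visit in record.usable_visits:
        if visit.age_years >= record.t0_years - _EPS:
            kept.append(visit)
            continue
        has_blood = visit_has_category(visit, catalog, BLOOD)
        has_urine = visit_has_category(visit, catalog, URINE)
        ok = (has_blood and has_urine) if require_both else (has_blood or has_urine)
        if ok:
            kept.append(visit)
    return replace(record, usable_visits=kept)


def filter_eligible(
    records: Sequence[LabeledRecord],
    catalog: AnalyteCatalog,
    cfg: FilterConfig,
) -> tuple[list[LabeledRecord], list[tuple[LabeledRecord, list[str]]]]:
    """Keep records with enough recent, lab-complete history before T0.

    A record is kept iff, among visits within ``window_years`` before T0
    (inclusive of the T0 visit): (a) there are at least ``min_visits_in_window``
    visits, (b) the fraction carrying >= 1 blood result is strictly greater
    than ``min_blood_fraction``, and (c) the fraction carrying >= 1 urine
    result is strictly greater than ``min_urine_fraction``.
    """
    kept: list[LabeledRecord] = []
    rejected: list[tuple[LabeledRecord, list[str]]] = []
    for rec in records:
        if rec.t0_years is None:
            raise ValueError(f"record {rec.patient_id} has no T0; filter after labeling")
        t0 = rec.t0_years
        in_window = [
            v
            for v in rec.usable_visits
            if t0 - cfg.window_years - _EPS <= v.age_years <= t0 + _EPS
        ]
        reasons = []
        if len(in_window) < cfg.min_visits_in_window:
            reasons.append("min_visits")
        else:
            blood_frac = np.mean([visit_has_category(v, catalog, BLOOD) for v in in_window])
            urine_frac = np.mean([visit_has_category(v, catalog, URINE) for v in in_window])
            if not blood_frac > cfg.min_blood_fraction:
                reasons.append("blood_fraction")
            if not urine_frac > cfg.min_urine_fraction:
                reasons.append("urine_fraction")
        if reasons:
            rejected.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, rejected


def split_train_test(
    records: Sequence[LabeledRecord], cfg: SplitConfig
) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    """Random stratified train/test split, deterministic given the seed.

    Within each status group, ``round(train_fraction * group size)`` records go
    to training.  Groups with fewer than two records go entirely to training
    (with a warning).  Original cohort order is preserved within each side.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.stratify_by_status:
        groups: dict[CKDStatus, list[int]] = {}
        for i, rec in enumerate(records):
            groups.setdefault(rec.status, []).append(i)
    else:
        groups = {CKDStatus.CKD: list(range(len(records)))}

    train_idx: set[int] = set()
    for status in sorted(groups, key=lambda s: s.value):
        idx = groups[status]
        if len(idx) < 2:
            warnings.warn(
                f"status group {status} has {len(idx)} record(s); assigning all to training"
            )
            train_idx.update(idx)
            continue
        n_train = int(round(cfg.train_fraction * len(idx)))
        perm = rng.permutation(len(idx))
        train_idx.update(idx[j] for j in perm[:n_train])
    train = [rec for i, rec in enumerate(records) if i in train_idx]
    test = [rec for i, rec in enumerate(records) if i not in train_idx]
    return train, test


def augment_truncations(
    records: Sequence[LabeledRecord], cfg: AugmentConfig
) -> list[LabeledRecord]:
    """Add truncated copies of each record (last k visits removed, k=1..n-1).

    By default a copy is kept only if the gap between its new last visit and
    T0 is at most ``max_gap_years``.  Labels and T0 are unchanged on copies;
    each copy carries ``provenance = (origin patient_id, k)``.  Intended for
    the training set only.
    """
    out: list[LabeledRecord] = []
    for rec in records:
        out.append(rec)
        if rec.status not in cfg.apply_to or rec.t0_years is None:
            continue
        n = len(rec.usable_visits)
        for k in range(1, n):
            trunc = rec.usable_visits[: n - k]
            gap = rec.t0_years - trunc[-1].age_years
            if cfg.drop_long_gaps and gap > cfg.max_gap_years + _EPS:
                continue
            out.append(
                replace(rec, usable_visits=list(trunc), provenance=(rec.patient_id, k))
            )
    return out
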