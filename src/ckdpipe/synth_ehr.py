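"""Synthetic longitudinal canine EHR cohorts.

Generates two latent clinical groups ("CKD", "no CKD") plus an ambiguous
"probable" group, with the statistical structure the downstream analysis
assumes: group-specific lab moments at the evaluation age, progressive renal
trajectories for CKD patients (creatinine/BUN/urine protein rising, USG and
weight falling toward diagnosis), realistic visit schedules, and missingness
with the urinalysis panel masked per visit as one block.

Trajectory model: each analyte's per-visit expectation interpolates linearly
from the healthy-group mean to the CKD-group evaluation-age mean over the
progression window (default 2 years before diagnosis); the per-visit SD is
interpolated the same way.  Values are drawn from a gamma distribution matched
to that mean/SD when the mean is within five SDs of zero (moment-exact and
non-negative, matching the right skew of clinical chemistry), and from a
normal otherwise.  USG is clipped to the physically meaningful [1.001, 1.065].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ehr_core import (
    URINE,
    AnalyteCatalog,
    CKDStatus,
    LabeledRecord,
    PatientRecord,
    VisitRecord,
    default_catalog,
)

__all__ = [
    "GROUP_CKD",
    "GROUP_NOCKD",
    "GROUP_PROBABLE",
    "PROBABLE_CKD_LEXICON",
    "Moments",
    "GroupParams",
    "CohortSpec",
    "GroundTruth",
    "default_cohort_spec",
    "simulate_patient",
    "simulate_cohort",
    "summarize_cohort",
]

GROUP_CKD = "CKD"
GROUP_NOCKD = "NO_CKD"
GROUP_PROBABLE = "PROBABLE"

#: Medical-note phrases that suggest CKD without a formal diagnosis.
PROBABLE_CKD_LEXICON = (
    "CKD",
    "azotemic",
    "Royal Canin Veterinary diet Renal",
    "Hill's prescription diet k/d",
)

_BENIGN_TOKENS = (
    "wellness_exam",
    "vaccination",
    "dental_cleaning",
    "ear_infection",
    "flea_prevention",
)

_BREEDS = (
    "mixed",
    "labrador_retriever",
    "chihuahua",
    "german_shepherd",
    "golden_retriever",
    "dachshund",
)

USG_FLOOR, USG_CEIL = 1.001, 1.065
_VALUE_FLOOR = 0.0

#: code written into the diagnosis_codes field of diagnosed visits.
CKD_DIAGNOSIS_CODE = "CKD"


@dataclass(frozen=True)
class Moments:
    mean_t0: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


@dataclass
class GroupParams:
    """Evaluation-age moments and visit-schedule parameters of one group."""

    analyte_moments: dict[str, Moments]
    age_t0: Moments
    weight: Moments
    mean_visits: float
    sex_ratio_m_to_f: float

    def __post_init__(self) -> None:
        if self.mean_visits < 2:
            raise ValueError("mean_visits must be >= 2")
        if self.sex_ratio_m_to_f <= 0:
            raise ValueError("sex_ratio_m_to_f must be > 0")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; ``seed`` makes it reproducible."""

    n_ckd: int
    n_nockd: int
    n_probable: int
    group_params: dict[str, GroupParams]
    seed: int
    progression_window_years: float = 2.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    visit_gap_mean_years: float = 0.5
    note_token_rate: float = 0.3
    weight_missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_ckd, self.n_nockd, self.n_probable) < 0:
            raise ValueError("group counts must be >= 0")
        if self.progression_window_years <= 0:
            raise ValueError("progression_window_years must be > 0")
        for name, p in self.missing_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing rate for {name} outside [0, 1]")
        if not 0.0 <= self.note_token_rate <= 1.0:
            raise ValueError("note_token_rate outside [0, 1]")


@dataclass
class GroundTruth:
    """Latent group and (for CKD) diagnosis age of every simulated patient."""

    groups: dict[str, str]
    diagnosis_age_years: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": list(self.groups),
                "group": [self.groups[p] for p in self.groups],
                "diagnosis_age_years": [self.diagnosis_age_years[p] for p in self.groups],
            }
        )


# Study-calibrated evaluation-age moments (training cohort): mean (SD) of the
# six model features per diagnosis group.
_CORE_MOMENTS = {
    GROUP_CKD: {
        "creatinine": (2.67, 1.86),
        "BUN": (56.23, 32.72),
        "USG": (1.020, 0.011),
        "urine_protein": (91.01, 180.81),
    },
    GROUP_NOCKD: {
        "creatinine": (1.09, 0.29),
        "BUN": (17.38, 5.59),
        "USG": (1.039, 0.012),
        "urine_protein": (49.52, 136.21),
    },
}
_AGE_WEIGHT = {
    GROUP_CKD: {"age": (11.56, 3.37), "weight": (13.04, 11.20), "visits": 15.2, "sex": 0.91},
    GROUP_NOCKD: {"age": (7.19, 2.93), "weight": (15.10, 12.42), "visits": 12.0, "sex": 1.08},
}

#: default missingness: ~10% per blood analyte, ~60% urinalysis block.
BLOOD_MISSING_RATE = 0.10
URINE_MISSING_RATE = 0.60


def _group_params(group: str, catalog: AnalyteCatalog) -> GroupParams:
    base = GROUP_CKD if group == GROUP_CKD else GROUP_NOCKD
    moments: dict[str, Moments] = {}
    for name, info in catalog.entries.items():
        if name in _CORE_MOMENTS[base]:
            m, s = _CORE_MOMENTS[base][name]
        else:
            # non-core analytes: stationary noise around the reference midpoint
            m = 0.5 * (info.normal_low + info.normal_high)
            s = 0.25 * (info.normal_high - info.normal_low)
        moments[name] = Moments(m, s)
    aw = dict(_AGE_WEIGHT[base])
    if group == GROUP_PROBABLE:
        aw["age"] = (9.0, 3.0)  # intermediate: ambiguous patients skew older
    return GroupParams(
        analyte_moments=moments,
        age_t0=Moments(*aw["age"]),
        weight=Moments(*aw["weight"]),
        mean_visits=aw["visits"],
        sex_ratio_m_to_f=aw["sex"],
    )


def default_cohort_spec(
    n_ckd: int,
    n_nockd: int,
    n_probable: int = 0,
    seed: int = 0,
    catalog: AnalyteCatalog | None = None,
) -> CohortSpec:
    """The study-calibrated cohort specification (Table-1 moments, ~10% blood
    and ~60% urine missingness, 2-year progression window)."""
    catalog = catalog or default_catalog()
    missing = {
        name: (URINE_MISSING_RATE if info.category == URINE else BLOOD_MISSING_RATE)
        for name, info in catalog.entries.items()
    }
    return CohortSpec(
        n_ckd=n_ckd,
        n_nockd=n_nockd,
        n_probable=n_probable,
        group_params={g: _group_params(g, catalog) for g in (GROUP_CKD, GROUP_NOCKD, GROUP_PROBABLE)},
        missing_rates=missing,
        seed=seed,
    )


def _draw_values(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray,
                 lo: float = _VALUE_FLOOR, hi: float | None = None) -> np.ndarray:
    """Moment-matched draws: gamma when mean/sd < 5 (skewed, non-negative),
    normal otherwise; clipped to [lo, hi]."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.empty_like(mean)
    skewed = mean < 5.0 * sd
    if np.any(skewed):
        m, s = mean[skewed], sd[skewed]
        shape = (m / s) ** 2
        out[skewed] = rng.gamma(shape, (s * s) / m)
    if np.any(~skewed):
        out[~skewed] = rng.normal(mean[~skewed], sd[~skewed])
    return np.clip(out, lo, hi)


def _visit_ages(rng: np.random.Generator, anchor: float, n_before: int,
                gap_mean: float, direction: int = -1) -> list[float]:
    """Ages stepping away from ``anchor`` with exponential gaps (min 0.02 y)."""
    gaps = np.maximum(rng.exponential(gap_mean, size=n_before), 0.02)
    ages = anchor + direction * np.cumsum(gaps)
    return [round(a, 6) for a in ages]


def simulate_patient(
    group: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    patient_id: str = "sim-0",
    catalog: AnalyteCatalog | None = None,
) -> PatientRecord:
    """Simulate one patient of the given latent group.

    CKD patients carry the diagnosis code at exactly one first diagnosis visit
    (repeated on ~half of any later visits) and ramp their renal analytes over
    the progression window; probable patients carry no diagnosis code but at
    least two CKD-suggesting signals; no-CKD patients are stationary around
    healthy means.
    """
    if group not in (GROUP_CKD, GROUP_NOCKD, GROUP_PROBABLE):
        raise ValueError(f"unknown group {group!r}")
    catalog = catalog or default_catalog()
    gp = spec.group_params[group]
    healthy = spec.group_params.get(GROUP_NOCKD, gp)

    p_male = gp.sex_ratio_m_to_f / (1.0 + gp.sex_ratio_m_to_f)
    sex = "male" if rng.random() < p_male else "female"
    breed = _BREEDS[rng.integers(len(_BREEDS))]

    n_visits = max(2, int(rng.poisson(gp.mean_visits)))
    t0 = float(np.clip(rng.normal(gp.age_t0.mean_t0, gp.age_t0.sd), 3.5, 20.0))

    if group == GROUP_CKD:
        n_post = min(int(rng.integers(0, 3)), n_visits - 2)
        n_pre = n_visits - 1 - n_post
        pre = [a for a in _visit_ages(rng, t0, n_pre, spec.visit_gap_mean_years) if a >= 1.5]
        post = [
            a
            for a in _visit_ages(rng, t0, n_post, 0.05, direction=+1)
            if a <= 22.0
        ]
        ages = sorted(pre) + [round(t0, 6)] + post
        diagnosis_age = round(t0, 6)
    else:
        last = min(t0 + 2.0, 21.9)
        earlier = [
            a
            for a in _visit_ages(rng, last, n_visits - 1, spec.visit_gap_mean_years)
            if a >= 1.5
        ]
        ages = sorted(earlier) + [round(last, 6)]
        diagnosis_age = None

    ages_arr = np.array(ages)
    if group == GROUP_CKD:
        ramp = np.clip(
            1.0 - (diagnosis_age - ages_arr) / spec.progression_window_years, 0.0, 1.0
        )
    else:
        ramp = np.zeros_like(ages_arr)

    n = len(ages)
    # weight: per-patient baseline; CKD patients lose ~10% over the window
    w0 = float(_draw_values(rng, np.array([gp.weight.mean_t0]), np.array([gp.weight.sd]), lo=0.5)[0])
    w_mean = w0 * (1.0 + 0.10 * (1.0 - ramp)) if group == GROUP_CKD else np.full(n, w0)
    weights = np.maximum(rng.normal(w_mean, 0.02 * w0), 0.3)
    weight_missing = rng.random(n) < spec.weight_missing_rate

    urine_names = set(catalog.urine_names)
    usg_rate = spec.missing_rates.get("USG", URINE_MISSING_RATE)
    urine_block_missing = rng.random(n) < usg_rate

    values: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    for name in catalog.names:
        m0 = healthy.analyte_moments[name]
        m1 = gp.analyte_moments[name]
        mean = m0.mean_t0 + ramp * (m1.mean_t0 - m0.mean_t0)
        sd = m0.sd + ramp * (m1.sd - m0.sd)
        lo, hi = (USG_FLOOR, USG_CEIL) if name == "USG" else (_VALUE_FLOOR, None)
        values[name] = _draw_values(rng, mean, np.maximum(sd, 1e-9), lo=lo, hi=hi)
        if name in urine_names:
            observed[name] = ~urine_block_missing
        else:
            rate = spec.missing_rates.get(name, BLOOD_MISSING_RATE)
            observed[name] = rng.random(n) >= rate

    visits: list[VisitRecord] = []
    for i, age in enumerate(ages):
        analytes = {
            name: float(values[name][i]) for name in catalog.names if observed[name][i]
        }
        tokens: set[str] = set()
        if rng.random() < spec.note_token_rate:
            tokens.add(_BENIGN_TOKENS[rng.integers(len(_BENIGN_TOKENS))])
        codes: set[str] = set()
        if group == GROUP_CKD and age >= diagnosis_age:
            if age == diagnosis_age or rng.random() < 0.5:
                codes.add(CKD_DIAGNOSIS_CODE)
        visits.append(
            VisitRecord(
                age_years=age,
                weight_kg=None if weight_missing[i] else float(round(weights[i], 3)),
                analytes=analytes,
                note_tokens=tokens,
                diagnosis_codes=codes,
            )
        )

    if group == GROUP_PROBABLE:
        _inject_probable_signals(visits, rng, catalog)

    return PatientRecord(patient_id=patient_id, sex=sex, breed=breed, visits=visits)


def _inject_probable_signals(
    visits: list[VisitRecord], rng: np.random.Generator, catalog: AnalyteCatalog
) -> None:
    """Guarantee >= 2 distinct CKD-suggesting signals without a diagnosis code."""
    n_signals = 2 + int(rng.random() < 0.3)
    kinds = list(rng.permutation(["note", "high_creatinine", "low_usg"]))[:n_signals]
    for kind in kinds:
        visit = visits[int(rng.integers(len(visits)))]
        if kind == "note":
            visit.note_tokens.add(PROBABLE_CKD_LEXICON[int(rng.integers(len(PROBABLE_CKD_LEXICON)))])
        elif kind == "high_creatinine":
            high = catalog["creatinine"].normal_high
            visit.analytes["creatinine"] = float(high * (1.2 + 0.8 * rng.random()))
        else:
            low = catalog["USG"].normal_low
            visit.analytes["USG"] = float(max(low - (0.002 + 0.008 * rng.random()), USG_FLOOR))


def simulate_cohort(
    spec: CohortSpec, catalog: AnalyteCatalog | None = None
) -> tuple[list[PatientRecord], GroundTruth]:
    """Simulate the full cohort: ``n_ckd + n_nockd + n_probable`` patients.

    Deterministic given ``spec.seed``; each patient draws from its own spawned
    random stream, so per-patient realisations do not depend on cohort size
    ordering quirks.
    """
    groups = (
        [GROUP_CKD] * spec.n_ckd
        + [GROUP_NOCKD] * spec.n_nockd
        + [GROUP_PROBABLE] * spec.n_probable
    )
    catalog = catalog or default_catalog()
    children = np.random.SeedSequence(spec.seed).spawn(len(groups))
    records: list[PatientRecord] = []
    gt_groups: dict[str, str] = {}
    gt_diag: dict[str, float | None] = {}
    for i, (group, child) in enumerate(zip(groups, children)):
        pid = f"dog-{i + 1:06d}"
        rec = simulate_patient(group, spec, np.random.default_rng(child), pid, catalog)
        records.append(rec)
        gt_groups[pid] = group
        diag = None
        for v in rec.visits:
            if CKD_DIAGNOSIS_CODE in v.diagnosis_codes:
                diag = v.age_years
                break
        gt_diag[pid] = diag
    return records, GroundTruth(groups=gt_groups, diagnosis_age_years=gt_diag)


def summarize_cohort(
    records: Sequence[LabeledRecord],
    catalog: AnalyteCatalog | None = None,
    analytes: Sequence[str] = ("creatinine", "BUN", "USG", "urine_protein"),
) -> pd.DataFrame:
    """Per-status-group demographics and lab summaries at the visit nearest T0.

    One row per status group: n, mean visits, male:female ratio, mean (SD) of
    age/weight and of each requested analyte at the visit nearest the
    evaluation age, plus percent-missing per analyte across usable visits.
    Empty groups yield a row of missing values.
    """
    catalog = catalog or default_catalog()
    rows = []
    statuses = [CKDStatus.CKD, CKDStatus.NO_CKD, CKDStatus.PROBABLE_CKD, CKDStatus.EXCLUDED]
    for status in statuses:
        group = [r for r in records if r.status == status]
        row: dict[str, float | str] = {"status": status.value, "n": len(group)}
        if not group:
            rows.append(row)
            continue
        row["mean_visits"] = float(np.mean([len(r.usable_visits) for r in group]))
        n_m = sum(r.patient.sex == "male" for r in group)
        n_f = len(group) - n_m
        row["sex_ratio_m_to_f"] = (n_m / n_f) if n_f else math.nan
        ref_ages, t0_visits = [], []
        for r in group:
            ref = r.t0_years if r.t0_years is not None else r.usable_visits[-1].age_years
            ref_ages.append(ref)
            t0_visits.append(min(r.usable_visits, key=lambda v: abs(v.age_years - ref)))
        def _ms(vals: list[float], label: str) -> None:
            arr = np.array(vals, dtype=float)
            arr = arr[~np.isnan(arr)]
            row[f"mean_{label}"] = float(arr.mean()) if arr.size else math.nan
            row[f"sd_{label}"] = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
        _ms(ref_ages, "age_t0")
        _ms([math.nan if v.weight_kg is None else v.weight_kg for v in t0_visits], "weight_t0")
        for name in analytes:
            _ms([v.analytes.get(name, math.nan) for v in t0_visits], f"{name}_t0")
            cells = [name in v.analytes for r in group for v in r.usable_visits]
            row[f"pct_missing_{name}"] = 100.0 * (1.0 - np.mean(cells)) if cells else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("status")
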