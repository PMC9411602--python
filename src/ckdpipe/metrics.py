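"""Evaluation mathematics: confusion metrics at the p = 0.5 cutoff,
prevalence-adjusted predictive values, normal-approximation confidence
intervals, and the T0 / horizon / stratified evaluation protocols.

Predictive values are computed from the standard Bayes identities

    PPV = se*pi / (se*pi + (1-sp)*(1-pi))
    NPV = sp*(1-pi) / (sp*(1-pi) + (1-se)*pi)

with the prevalence ``pi`` supplied externally (default 0.83%, a realistic
population prevalence of canine CKD), because sensitivity and specificity are
estimated on a case-enriched test set whose sample prevalence is far from the
population's.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ehr_core import CKDStatus, LabeledRecord
from .rnn import TrainedNet, build_sequences, predict_proba

__all__ = [
    "ConfusionCounts",
    "DiagnosticSummary",
    "LifeStageBoundaries",
    "DEFAULT_PREVALENCE",
    "confusion",
    "basic_rates",
    "predictive_values",
    "wald_ci",
    "estimate_prevalence",
    "life_stage",
    "summary_from_counts",
    "evaluate_at_t0",
    "horizon_evaluation",
    "stratified_report",
    "summaries_to_frame",
]

_EPS = 1e-9

#: overall-population CKD prevalence used for the headline predictive values.
DEFAULT_PREVALENCE = 0.0083


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticSummary:
    """Rates with 95% normal-approximation intervals plus predictive values."""

    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    ppv: float
    npv: float
    prevalence_used: float
    n_pos: int
    n_neg: int


def confusion(
    labels: Sequence[int], probs: Sequence[float], cutoff: float = 0.5
) -> ConfusionCounts:
    """Tally the confusion matrix; p >= cutoff predicts CKD (ties positive)."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {probs.shape} probs")
    pred = probs >= cutoff
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def basic_rates(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); NaN where a denominator is empty."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    acc = (c.tp + c.tn) / c.total if c.total else math.nan
    return sens, spec, acc


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Prevalence-adjusted (PPV, NPV); NaN for degenerate 0/0 combinations."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    ppv_num = sensitivity * prevalence
    ppv_den = ppv_num + (1.0 - specificity) * (1.0 - prevalence)
    npv_num = specificity * (1.0 - prevalence)
    npv_den = npv_num + (1.0 - sensitivity) * prevalence
    ppv = ppv_num / ppv_den if ppv_den > 0 else math.nan
    npv = npv_num / npv_den if npv_den > 0 else math.nan
    return ppv, npv


def wald_ci(
    p: float, n: int, level: float = 0.95, rounded_z: bool = False
) -> tuple[float, float]:
    """Normal-approximation interval p +/- z*sqrt(p(1-p)/n), clipped to [0,1].

    ``rounded_z`` substitutes the conventional 1.96 for the exact quantile.
    """
    if n <= 0:
        return (math.nan, math.nan)
    z = 1.96 if rounded_z else float(norm.ppf(0.5 + level / 2.0))
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def estimate_prevalence(n_cases: int, n_population: int) -> float:
    if n_population <= 0:
        raise ValueError("population must be > 0")
    if not 0 <= n_cases <= n_population:
        raise ValueError("cases must lie in [0, population]")
    return n_cases / n_population


@dataclass(frozen=True)
class LifeStageBoundaries:
    """Canine life stages by age (years): boundaries belong to the older stage."""

    edges: tuple[float, float, float] = (6.5, 9.75, 13.0)
    labels: tuple[str, str, str, str] = ("adult", "mature", "senior", "geriatric")
    min_age: float = 1.5

    def __post_init__(self) -> None:
        if list(self.edges) != sorted(self.edges) or len(self.labels) != len(self.edges) + 1:
            raise ValueError("edges must be sorted and labels one longer than edges")


def life_stage(age_years: float, b: LifeStageBoundaries | None = None) -> str:
    b = b or LifeStageBoundaries()
    if age_years < b.min_age:
        raise ValueError(f"age {age_years} below the cohort minimum {b.min_age}")
    return b.labels[bisect_right(b.edges, age_years)]


def summary_from_counts(
    c: ConfusionCounts, prevalence: float, level: float = 0.95, rounded_z: bool = False
) -> DiagnosticSummary:
    sens, spec, acc = basic_rates(c)
    if math.isnan(sens) or math.isnan(spec):
        ppv, npv = math.nan, math.nan
    else:
        ppv, npv = predictive_values(sens, spec, prevalence)
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=wald_ci(sens, c.tp + c.fn, level, rounded_z) if not math.isnan(sens) else (math.nan, math.nan),
        specificity_ci=wald_ci(spec, c.tn + c.fp, level, rounded_z) if not math.isnan(spec) else (math.nan, math.nan),
        accuracy_ci=wald_ci(acc, c.total, level, rounded_z) if not math.isnan(acc) else (math.nan, math.nan),
        ppv=ppv,
        npv=npv,
        prevalence_used=prevalence,
        n_pos=c.tp + c.fn,
        n_neg=c.tn + c.fp,
    )


# ---------------------------------------------------------------------------
# Protocols over labeled records
# ---------------------------------------------------------------------------

def _score(net: TrainedNet, records: Sequence[LabeledRecord]) -> tuple[np.ndarray, np.ndarray]:
    samples = build_sequences(records, net.feature_spec)
    labels = np.array([s.label for s in samples])
    return labels, predict_proba(net, samples)


def evaluate_at_t0(
    net: TrainedNet,
    test: Sequence[LabeledRecord],
    t0_window_years: float = 0.25,
    prevalence: float = DEFAULT_PREVALENCE,
) -> DiagnosticSummary:
    """Diagnostic performance at the evaluation age.

    Restricts to test records with a usable visit within ``t0_window_years``
    of T0 (a prediction made long before T0 is a horizon question, not a
    detection-at-diagnosis question), scores the full usable sequences, and
    summarises with the supplied prevalence.
    """
    eligible = [
        r
        for r in test
        if r.t0_years is not None
        and any(abs(v.age_years - r.t0_years) <= t0_window_years + _EPS for v in r.usable_visits)
    ]
    if not eligible:
        raise ValueError("no test records with a visit near T0")
    labels, probs = _score(net, eligible)
    return summary_from_counts(confusion(labels, probs), prevalence)


def horizon_evaluation(
    net: TrainedNet,
    test: Sequence[LabeledRecord],
    horizons: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5),
    prevalence: float = DEFAULT_PREVALENCE,
    count_empty_as_missed: bool = False,
) -> dict[float, DiagnosticSummary]:
    """Early-detection performance as a function of the prediction horizon.

    For each horizon h, CKD records keep only visits at least h years before
    T0; records left without visits are dropped from that horizon's
    sensitivity denominator (or, with ``count_empty_as_missed``, counted as
    false negatives).  NO_CKD records are scored untruncated — their T0 is an
    administrative anchor with no clinical trajectory, so specificity does not
    vary meaningfully with the horizon.
    """
    ckd = [r for r in test if r.status == CKDStatus.CKD]
    nockd = [r for r in test if r.status == CKDStatus.NO_CKD]
    if nockd:
        neg_labels, neg_probs = _score(net, nockd)
    else:
        neg_labels, neg_probs = np.array([], dtype=int), np.array([])

    out: dict[float, DiagnosticSummary] = {}
    for h in horizons:
        if h < 0:
            raise ValueError("horizons must be >= 0")
        truncated, n_empty = [], 0
        for r in ckd:
            vis = [v for v in r.usable_visits if v.age_years <= r.t0_years - h + _EPS]
            if vis:
                truncated.append(replace(r, usable_visits=vis))
            else:
                n_empty += 1
        if truncated:
            pos_labels, pos_probs = _score(net, truncated)
        else:
            pos_labels, pos_probs = np.array([], dtype=int), np.array([])
        c = confusion(
            np.concatenate([pos_labels, neg_labels]),
            np.concatenate([pos_probs, neg_probs]),
        )
        if count_empty_as_missed:
            c = ConfusionCounts(tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn + n_empty)
        out[float(h)] = summary_from_counts(c, prevalence)
    return out


def _stratum_key(record: LabeledRecord, strata: str):
    if strata == "age-year":
        return int(math.floor(record.t0_years))
    if strata == "life-stage":
        return life_stage(record.t0_years)
    if strata == "visit-count":
        return sum(v.age_years <= record.t0_years + _EPS for v in record.usable_visits)
    raise ValueError(f"unknown strata {strata!r}")


def stratified_report(
    net: TrainedNet,
    test: Sequence[LabeledRecord],
    strata: str = "life-stage",
    prevalence_by_stratum: dict | None = None,
    default_prevalence: float = DEFAULT_PREVALENCE,
) -> pd.DataFrame:
    """Per-stratum DiagnosticSummary table (age-year, life-stage or visit-count
    strata); prevalence can be supplied per stratum, Table-2 style."""
    prevalence_by_stratum = prevalence_by_stratum or {}
    keys: dict[object, list[LabeledRecord]] = {}
    for r in test:
        if r.t0_years is None:
            raise ValueError(f"record {r.patient_id} has no T0")
        keys.setdefault(_stratum_key(r, strata), []).append(r)
    rows = []
    for key in sorted(keys):
        group = keys[key]
        labels, probs = _score(net, group)
        prev = prevalence_by_stratum.get(key, default_prevalence)
        s = summary_from_counts(confusion(labels, probs), prev)
        rows.append({"stratum": key, "n": len(group), **_summary_dict(s)})
    return pd.DataFrame(rows)


def _summary_dict(s: DiagnosticSummary) -> dict[str, float]:
    return {
        "sensitivity": s.sensitivity,
        "sensitivity_lo": s.sensitivity_ci[0],
        "sensitivity_hi": s.sensitivity_ci[1],
        "specificity": s.specificity,
        "specificity_lo": s.specificity_ci[0],
        "specificity_hi": s.specificity_ci[1],
        "accuracy": s.accuracy,
        "ppv": s.ppv,
        "npv": s.npv,
        "prevalence_used": s.prevalence_used,
        "n_pos": s.n_pos,
        "n_neg": s.n_neg,
    }


def summaries_to_frame(summaries: dict[float, DiagnosticSummary]) -> pd.DataFrame:
    """Horizon table -> DataFrame (one row per horizon)."""
    rows = [
        {"horizon_years": h, **_summary_dict(s)} for h, s in sorted(summaries.items())
    ]
    return pd.DataFrame(rows)
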