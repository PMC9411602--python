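"""Chained nonparametric imputation of missing blood/urine values.

The scheme follows the MissForest recipe: initialise missing cells at column
means, then repeatedly regress each analyte on all others with a tree-ensemble
regressor (columns visited in order of ascending missingness), updating the
missing cells, until the normalised change of the imputed values drops below a
tolerance or the iteration cap is reached.  The fitted per-column regressors
are retained so new visits can be imputed consistently.

The imputer never sees CKD status, T0 or diagnosis codes — its inputs are
per-visit analyte matrices only, which makes label leakage structurally
impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from .ehr_core import AnalyteCatalog, ConfigurationError, LabeledRecord

__all__ = [
    "ImputerConfig",
    "ImputerModel",
    "ImputationError",
    "build_visit_matrix",
    "fit_imputer",
    "transform_matrix",
    "impute_missing",
]

USG_FLOOR, USG_CEIL = 1.001, 1.065


class ImputationError(ValueError):
    """Imputation cannot proceed (e.g. an all-missing column)."""


@dataclass
class ImputerConfig:
    """``method`` is ``"forest"`` (random-forest regressors, the default) or
    ``"linear"`` (ridge regressors; much faster, for quick runs and tests).
    ``max_fit_rows`` subsamples rows for each per-column fit to bound cost on
    large cohorts; prediction always covers every missing cell."""

    max_iter: int = 10
    tol: float = 1e-3
    trees: int = 50
    seed: int = 0
    method: str = "forest"
    max_fit_rows: int = 5000

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.trees < 1 or self.tol <= 0:
            raise ValueError("max_iter, trees must be >= 1 and tol > 0")
        if self.method not in ("forest", "linear"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ImputerModel:
    """Fitted chained imputer: per-analyte regressors, column means, the
    column visiting order, iterations run and the convergence trace."""

    columns: tuple[str, ...]
    col_means: dict[str, float]
    regressors: dict[str, object]
    col_order: tuple[str, ...]
    n_iter: int
    trace: list[float]
    cfg: ImputerConfig

    def known_columns(self) -> set[str]:
        return set(self.columns)


def build_visit_matrix(
    records: Sequence[LabeledRecord], catalog: AnalyteCatalog
) -> pd.DataFrame:
    """Cross-sectional per-visit matrix of blood/urine analytes (NaN = missing).

    Rows are indexed by (record position, visit position within usable_visits).
    """
    columns = list(catalog.blood_names) + list(catalog.urine_names)
    index, data = [], []
    for i, rec in enumerate(records):
        for j, visit in enumerate(rec.usable_visits):
            index.append((i, j))
            data.append([visit.analytes.get(c, np.nan) for c in columns])
    if not index:
        return pd.DataFrame(columns=columns, index=pd.MultiIndex.from_arrays([[], []]))
    return pd.DataFrame(data, columns=columns, index=pd.MultiIndex.from_tuples(index))


def _make_estimator(cfg: ImputerConfig, seed: int):
    if cfg.method == "linear":
        return Ridge(alpha=1.0)
    return RandomForestRegressor(
        n_estimators=cfg.trees,
        random_state=seed,
        n_jobs=1,
        min_samples_leaf=5,
    )


def fit_imputer(visit_matrix: pd.DataFrame, cfg: ImputerConfig | None = None) -> ImputerModel:
    """Fit the chained imputer on a per-visit analyte matrix.

    Raises :class:`ImputationError` for an all-missing column and requires at
    least two columns.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or ImputerConfig()
    if visit_matrix.shape[1] < 2:
        raise ImputationError("need at least 2 analyte columns to impute")
    all_missing = [c for c in visit_matrix.columns if visit_matrix[c].isna().all()]
    if all_missing:
        raise ImputationError(f"column(s) with no observed values: {all_missing}")

    columns = tuple(visit_matrix.columns)
    means = visit_matrix.mean()
    missing_mask = visit_matrix.isna()
    # visit columns in order of ascending missingness (best-informed first)
    col_order = tuple(missing_mask.sum().sort_values(kind="stable").index)

    X = visit_matrix.fillna(means).to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(columns)}
    mask = missing_mask.to_numpy()
    any_missing = bool(mask.any())

    rng = np.random.default_rng(cfg.seed)
    regressors: dict[str, object] = {}
    trace: list[float] = []
    n_iter = 0
    for it in range(cfg.max_iter):
        prev_imputed = X[mask].copy() if any_missing else None
        for c in col_order:
            j = col_idx[c]
            others = [k for k in range(X.shape[1]) if k != j]
            obs = ~mask[:, j]
            est = _make_estimator(cfg, int(rng.integers(2**31 - 1)))
            obs_idx = np.flatnonzero(obs)
            if obs_idx.size > cfg.max_fit_rows:
                obs_idx = rng.choice(obs_idx, size=cfg.max_fit_rows, replace=False)
            est.fit(X[np.ix_(obs_idx, others)], X[obs_idx, j])
            regressors[c] = est
            miss_idx = np.flatnonzero(mask[:, j])
            if miss_idx.size:
                X[miss_idx, j] = est.predict(X[np.ix_(miss_idx, others)])
        if not any_missing:
            break
        n_iter = it + 1
        new_imputed = X[mask]
        denom = float(np.sum(new_imputed**2)) or 1.0
        delta = float(np.sum((new_imputed - prev_imputed) ** 2)) / denom
        trace.append(delta)
        if delta < cfg.tol:
            break
    return ImputerModel(
        columns=columns,
        col_means={c: float(means[c]) for c in columns},
        regressors=regressors,
        col_order=col_order,
        n_iter=n_iter,
        trace=trace,
        cfg=cfg,
    )


def transform_matrix(model: ImputerModel, visit_matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells of a compatible matrix using the fitted regressors.

    Observed cells are returned bit-identical; runs the chained updates with
    the stored regressors until the model's own tolerance or iteration cap.
    """
    unknown = [c for c in visit_matrix.columns if c not in model.known_columns()]
    if unknown:
        raise ConfigurationError(f"analyte(s) unknown to the imputer: {unknown}")
    out = visit_matrix.reindex(columns=list(model.columns))
    mask_df = out.isna()
    X = out.fillna(pd.Series(model.col_means)).to_numpy(dtype=float)
    mask = mask_df.to_numpy()
    if not mask.any():
        return visit_matrix.copy()
    col_idx = {c: i for i, c in enumerate(model.columns)}
    for _ in range(max(1, model.n_iter)):
        prev = X[mask].copy()
        for c in model.col_order:
            j = col_idx[c]
            miss_idx = np.flatnonzero(mask[:, j])
            if not miss_idx.size:
                continue
            others = [k for k in range(X.shape[1]) if k != j]
            X[miss_idx, j] = model.regressors[c].predict(X[np.ix_(miss_idx, others)])
        new = X[mask]
        denom = float(np.sum(new**2)) or 1.0
        if float(np.sum((new - prev) ** 2)) / denom < model.cfg.tol:
            break
    result = pd.DataFrame(X, columns=list(model.columns), index=visit_matrix.index)
    # restore observed cells exactly (no float round-trip through the solver)
    result[~mask_df] = visit_matrix.reindex(columns=list(model.columns))
    return result


def impute_missing(
    records: Sequence[LabeledRecord],
    model: ImputerModel,
    catalog: AnalyteCatalog,
) -> list[LabeledRecord]:
    """Return records with every blood/urine cell of every usable visit filled.

    Observed values are preserved exactly; imputed USG is clipped to
    [1.001, 1.065] and all other imputed analytes to be non-negative.
    """
    matrix = build_visit_matrix(records, catalog)
    if matrix.empty:
        return [replace(r) for r in records]
    filled = transform_matrix(model, matrix)
    out: list[LabeledRecord] = []
    for i, rec in enumerate(records):
        new_visits = []
        for j, visit in enumerate(rec.usable_visits):
            analytes = dict(visit.analytes)
            row = filled.loc[(i, j)]
            for name in model.columns:
                if name in analytes:
                    continue
                v = float(row[name])
                if name == "USG":
                    v = float(np.clip(v, USG_FLOOR, USG_CEIL))
                else:
                    v = max(v, 0.0)
                analytes[name] = v
            new_visits.append(replace(visit, analytes=analytes,
                                      note_tokens=set(visit.note_tokens),
                                      diagnosis_codes=set(visit.diagnosis_codes)))
        out.append(replace(rec, usable_visits=new_visits))
    return out
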