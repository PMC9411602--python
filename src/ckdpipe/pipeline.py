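"""End-to-end study replica: simulate -> label -> mask -> filter -> split ->
impute -> augment -> train -> evaluate, behind one configuration object.

Every stage's record counts are reconciled in a run manifest (the funnel), and
one global seed derives independent per-stage seeds through a spawned numpy
SeedSequence, so any stage can be rerun in isolation reproducibly.  Probable-
CKD records are labeled and counted but excluded from training and from the
headline sensitivity/specificity; excluded records leave the funnel at
labeling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import impute as impute_mod
from . import labeling as labeling_mod
from . import metrics as metrics_mod
from . import rnn as rnn_mod
from . import synth_ehr
from .ehr_core import AnalyteCatalog, CKDStatus, LabeledRecord, default_catalog

__all__ = ["RunConfig", "PipelineResult", "derive_stage_seeds", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "split", "impute", "train")


@dataclass
class RunConfig:
    """Nested configuration for the full pipeline run."""

    n_ckd: int = 500
    n_nockd: int = 500
    n_probable: int = 50
    seed: int = 0
    outdir: str | None = None

    rules: labeling_mod.LabelingRules = field(default_factory=labeling_mod.LabelingRules)
    filter: cohort_mod.FilterConfig = field(default_factory=cohort_mod.FilterConfig)
    split: cohort_mod.SplitConfig = field(default_factory=cohort_mod.SplitConfig)
    augment: cohort_mod.AugmentConfig = field(default_factory=cohort_mod.AugmentConfig)
    imputer: impute_mod.ImputerConfig = field(default_factory=impute_mod.ImputerConfig)
    net: rnn_mod.NetConfig = field(default_factory=rnn_mod.NetConfig)
    features: tuple[str, ...] = rnn_mod.DEFAULT_FEATURES

    impute_before_split: bool = False  # fit the imputer on the full cohort pre-split
    horizons: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
    prevalence: float = metrics_mod.DEFAULT_PREVALENCE
    t0_window_years: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict[str, Any] = {}
        section_types = {
            "rules": labeling_mod.LabelingRules,
            "filter": cohort_mod.FilterConfig,
            "split": cohort_mod.SplitConfig,
            "augment": cohort_mod.AugmentConfig,
            "imputer": impute_mod.ImputerConfig,
            "net": rnn_mod.NetConfig,
        }
        for key, value in raw.items():
            if key in section_types:
                if key == "rules":
                    for f in ("diagnosis_codes_ckd", "probable_note_tokens", "risk_note_tokens"):
                        if f in value:
                            value[f] = set(value[f])
                if key == "augment" and "apply_to" in value:
                    value["apply_to"] = {CKDStatus(s) for s in value["apply_to"]}
                if key == "net" and "hidden_layers" in value:
                    value["hidden_layers"] = tuple(value["hidden_layers"])
                kwargs[key] = section_types[key](**value)
            elif key in ("features", "horizons"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    net: rnn_mod.TrainedNet
    t0_summary: metrics_mod.DiagnosticSummary
    horizon_summaries: dict[float, metrics_mod.DiagnosticSummary]
    strata_table: Any
    manifest: dict
    test_records: list[LabeledRecord]
    train_records: list[LabeledRecord]


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """One independent sub-seed (< 2**31) per randomised stage."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        stage: int(np.random.default_rng(child).integers(2**31 - 1))
        for stage, child in zip(_STAGES, children)
    }


def _config_dict(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (set, frozenset)):
            return sorted(str(x) for x in obj)
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, CKDStatus):
            return obj.value
        return obj

    return {f.name: clean(getattr(config, f.name)) for f in dataclasses.fields(config)}


def run_pipeline(
    config: RunConfig, catalog: AnalyteCatalog | None = None
) -> PipelineResult:
    """Execute all stages in order and return artefacts plus the manifest."""
    catalog = catalog or default_catalog()
    seeds = derive_stage_seeds(config.seed)
    funnel: dict[str, Any] = {}

    # --- simulate ---------------------------------------------------------
    spec = synth_ehr.default_cohort_spec(
        config.n_ckd, config.n_nockd, config.n_probable, seed=seeds["simulate"], catalog=catalog
    )
    records, ground_truth = synth_ehr.simulate_cohort(spec, catalog)
    funnel["simulated"] = len(records)
    logger.info("simulate: %d patients", len(records))

    # --- label ------------------------------------------------------------
    labeled = labeling_mod.label_cohort(records, catalog, config.rules)
    by_status = {
        s.value: sum(r.status == s for r in labeled) for s in CKDStatus
    }
    funnel["labeled"] = by_status
    assert sum(by_status.values()) == len(records)
    modelable = [r for r in labeled if r.status in (CKDStatus.CKD, CKDStatus.NO_CKD)]
    logger.info("label: %s", by_status)

    # --- mask outliers / drop lab-free visits / eligibility ---------------
    pop_sd = cohort_mod.compute_population_sd(modelable, catalog)
    masked = cohort_mod.mask_outliers(modelable, catalog, pop_sd, config.filter)
    masked = [cohort_mod.drop_lab_free_visits(r, catalog) for r in masked]
    n_before_trim = len(masked)
    masked = [r for r in masked if r.usable_visits]
    funnel["empty_after_trim"] = n_before_trim - len(masked)
    kept, rejected = cohort_mod.filter_eligible(masked, catalog, config.filter)
    funnel["eligible"] = len(kept)
    funnel["rejected"] = len(rejected)
    funnel["rejection_reasons"] = {}
    for _, reasons in rejected:
        for reason in reasons:
            funnel["rejection_reasons"][reason] = funnel["rejection_reasons"].get(reason, 0) + 1
    logger.info("filter: kept %d, rejected %d", len(kept), len(rejected))

    # --- split ------------------------------------------------------------
    split_cfg = dataclasses.replace(config.split, seed=seeds["split"])
    train_recs, test_recs = cohort_mod.split_train_test(kept, split_cfg)
    funnel["train"] = len(train_recs)
    funnel["test"] = len(test_recs)

    # --- impute -----------------------------------------------------------
    imp_cfg = dataclasses.replace(config.imputer, seed=seeds["impute"])
    fit_on = kept if config.impute_before_split else train_recs
    imputer = impute_mod.fit_imputer(
        impute_mod.build_visit_matrix(fit_on, catalog), imp_cfg
    )
    train_recs = impute_mod.impute_missing(train_recs, imputer, catalog)
    test_recs = impute_mod.impute_missing(test_recs, imputer, catalog)
    funnel["imputer_iterations"] = imputer.n_iter
    logger.info("impute: %d iterations, trace %s", imputer.n_iter, imputer.trace)

    # --- augment + train --------------------------------------------------
    augmented = cohort_mod.augment_truncations(train_recs, config.augment)
    funnel["train_augmented"] = len(augmented)
    feature_spec = rnn_mod.fit_feature_spec(augmented, config.features)
    samples = rnn_mod.build_sequences(augmented, feature_spec)
    net_cfg = dataclasses.replace(config.net, seed=seeds["train"])
    net = rnn_mod.train(net_cfg, feature_spec, samples)
    logger.info("train: %d samples, final loss %.4f", len(samples), net.loss_trace[-1])

    # --- evaluate ---------------------------------------------------------
    t0_summary = metrics_mod.evaluate_at_t0(
        net, test_recs, config.t0_window_years, config.prevalence
    )
    horizon = metrics_mod.horizon_evaluation(
        net, test_recs, config.horizons, config.prevalence
    )
    strata = metrics_mod.stratified_report(
        net, test_recs, "life-stage", default_prevalence=config.prevalence
    )

    config_dict = _config_dict(config)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": seeds,
        "funnel": funnel,
        "t0_sensitivity": round(t0_summary.sensitivity, 6),
        "t0_specificity": round(t0_summary.specificity, 6),
        "t0_accuracy": round(t0_summary.accuracy, 6),
    }

    if config.outdir:
        _write_artifacts(config, manifest, net, t0_summary, horizon, strata, labeled, catalog)

    return PipelineResult(
        net=net,
        t0_summary=t0_summary,
        horizon_summaries=horizon,
        strata_table=strata,
        manifest=manifest,
        test_records=test_recs,
        train_records=train_recs,
    )


def _write_artifacts(config, manifest, net, t0_summary, horizon, strata, labeled, catalog):
    import pandas as pd

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    rnn_mod.save_net(net, outdir / "model.json")
    pd.DataFrame([metrics_mod._summary_dict(t0_summary)]).to_csv(
        outdir / "t0_summary.csv", index=False
    )
    metrics_mod.summaries_to_frame(horizon).to_csv(outdir / "horizon_table.csv", index=False)
    strata.to_csv(outdir / "life_stage_table.csv", index=False)
    synth_ehr.summarize_cohort(labeled, catalog).to_csv(outdir / "cohort_summary.csv")
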