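"""Shared fixtures: the default catalog, record builders, and one full
study-scale pipeline run reused by the end-to-end performance tests."""

from __future__ import annotations

import pytest

from ckdpipe import default_catalog
from ckdpipe.ehr_core import LabeledRecord, PatientRecord, VisitRecord
from ckdpipe.impute import ImputerConfig
from ckdpipe.labeling import LabelingRules
from ckdpipe.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def rules():
    return LabelingRules()


def make_visit(age, weight=10.0, analytes=None, notes=(), codes=()):
    return VisitRecord(
        age_years=age,
        weight_kg=weight,
        analytes=dict(analytes or {}),
        note_tokens=set(notes),
        diagnosis_codes=set(codes),
    )


def make_patient(pid="p1", visits=(), sex="female", breed="mixed"):
    return PatientRecord(patient_id=pid, sex=sex, breed=breed, visits=list(visits))


def make_labeled(pid, status, t0, visit_args, **kwargs):
    visits = [make_visit(*a) if isinstance(a, tuple) else make_visit(a) for a in visit_args]
    return LabeledRecord(
        patient=make_patient(pid, visits),
        status=status,
        t0_years=t0,
        usable_visits=list(visits),
        **kwargs,
    )


@pytest.fixture(scope="session")
def study_run():
    """The default study-scale synthetic run: 500 CKD + 500 no-CKD (+50
    probable), fixed seed, 5-3-3 net over 8 epochs, desk-scale imputer."""
    config = RunConfig(
        n_ckd=500,
        n_nockd=500,
        n_probable=50,
        seed=0,
        imputer=ImputerConfig(method="forest", trees=15, max_iter=3, max_fit_rows=2000),
    )
    return config, run_pipeline(config)
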