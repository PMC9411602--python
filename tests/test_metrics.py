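"""Evaluation mathematics: confusion rates, prevalence-adjusted predictive
values, normal-approximation intervals, life stages, and the T0/horizon/
stratified protocols."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdpipe.ehr_core import CKDStatus
from ckdpipe.metrics import (
    ConfusionCounts,
    LifeStageBoundaries,
    basic_rates,
    confusion,
    estimate_prevalence,
    evaluate_at_t0,
    horizon_evaluation,
    life_stage,
    predictive_values,
    stratified_report,
    summaries_to_frame,
    wald_ci,
)
from ckdpipe.rnn import FeatureSpec, NetConfig, TrainedNet

from .conftest import make_labeled


class TestConfusion:
    def test_basic_tally(self):
        c = confusion([1, 0], [0.6, 0.4])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_cutoff_tie_is_positive(self):
        c = confusion([0], [0.5])
        assert c.fp == 1

    def test_empty(self):
        c = confusion([], [])
        assert c.total == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1], [0.5, 0.5])


class TestRates:
    def test_detection_rates_from_study_counts(self):
        sens, _, _ = basic_rates(ConfusionCounts(tp=9955, fp=0, tn=0, fn=934))
        assert round(100 * sens, 2) == 91.42
        _, spec, _ = basic_rates(ConfusionCounts(tp=0, fp=121, tn=4142, fn=0))
        assert round(100 * spec, 2) == 97.16
        _, _, acc = basic_rates(ConfusionCounts(tp=9955, fp=121, tn=4142, fn=934))
        assert round(100 * acc, 2) == 93.04

    def test_empty_denominator_is_missing(self):
        sens, spec, acc = basic_rates(ConfusionCounts(tp=0, fp=0, tn=3, fn=0))
        assert math.isnan(sens) and spec == 1.0 and acc == 1.0


class TestPredictiveValues:
    def test_low_prevalence_adjustment(self):
        ppv, npv = predictive_values(0.9142, 0.9716, 0.0083)
        assert round(ppv, 4) == 0.2122
        assert round(npv, 4) == 0.9993

    def test_perfect_test(self):
        assert predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_long_horizon_npv(self):
        ppv, npv = predictive_values(0.2320, 0.9965, 0.0083)
        assert round(npv, 4) == 0.9936
        assert round(ppv, 4) == pytest.approx(0.3568, abs=5e-4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    def test_matches_confusion_matrix_at_sample_prevalence(self, tp, fp, tn, fn):
        """At the sample prevalence the Bayes formulas must reduce to the
        plain confusion-matrix PPV/NPV."""
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        if c.total == 0 or (tp + fn) == 0 or (tn + fp) == 0:
            return
        sens, spec, _ = basic_rates(c)
        prev = (tp + fn) / c.total
        ppv, npv = predictive_values(sens, spec, prev)
        if tp + fp:
            assert ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
        if tn + fn:
            assert npv == pytest.approx(tn / (tn + fn), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        sens=st.floats(0.05, 0.99), spec=st.floats(0.05, 0.99),
        p1=st.floats(0.01, 0.98), dp=st.floats(0.001, 0.01),
    )
    def test_monotone_in_prevalence(self, sens, spec, p1, dp):
        ppv1, npv1 = predictive_values(sens, spec, p1)
        ppv2, npv2 = predictive_values(sens, spec, min(p1 + dp, 0.999))
        assert ppv2 >= ppv1 and npv2 <= npv1


class TestWaldCI:
    def test_half_width_closed_form(self):
        lo, hi = wald_ci(0.5, 100, rounded_z=True)
        assert (hi - lo) / 2 == pytest.approx(0.098, abs=1e-4)

    def test_degenerate_variance(self):
        assert wald_ci(1.0, 50) == (1.0, 1.0)

    def test_large_n_closed_form(self):
        p = 9955 / 10889
        lo, hi = wald_ci(p, 10889, rounded_z=True)
        assert lo == pytest.approx(0.9089, abs=1e-4)
        assert hi == pytest.approx(0.9195, abs=1e-4)

    def test_width_shrinks_with_n(self):
        widths = [np.diff(wald_ci(0.3, n))[0] for n in (10**2, 10**4, 10**6)]
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 1e-2

    def test_exact_quantile_vs_rounded(self):
        lo_exact, _ = wald_ci(0.5, 100, rounded_z=False)
        lo_round, _ = wald_ci(0.5, 100, rounded_z=True)
        assert lo_exact != lo_round
        assert lo_exact == pytest.approx(lo_round, abs=1e-4)


def test_prevalence_arithmetic():
    assert round(100 * estimate_prevalence(54098, 6_500_000), 2) == 0.83
    assert estimate_prevalence(0, 100) == 0.0
    assert estimate_prevalence(100, 100) == 1.0
    with pytest.raises(ValueError):
        estimate_prevalence(1, 0)


class TestLifeStage:
    @pytest.mark.parametrize(
        "age,stage",
        [(5.0, "adult"), (6.4, "adult"), (6.5, "mature"), (9.75, "senior"),
         (12.9, "senior"), (13.0, "geriatric"), (14.0, "geriatric")],
    )
    def test_boundaries(self, age, stage):
        assert life_stage(age) == stage

    def test_below_cohort_minimum(self):
        with pytest.raises(ValueError):
            life_stage(1.4)

    def test_custom_boundaries_validated(self):
        with pytest.raises(ValueError):
            LifeStageBoundaries(edges=(9.75, 6.5, 13.0))


# ---------------------------------------------------------------------------
# Protocol tests with a hand-built single-feature net whose output tracks the
# creatinine of the final visit: p(CKD) ~ softmax(10*tanh(5*z_cr)).
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def threshold_net():
    params = {
        "W0": np.array([[5.0]]),
        "U0": np.array([[0.0]]),
        "b0": np.array([0.0]),
        "V": np.array([[10.0], [-10.0]]),
        "c": np.array([0.0, 0.0]),
    }
    spec = FeatureSpec(names=("creatinine",), scaler={"creatinine": (1.5, 1.0)})
    return TrainedNet(params=params, feature_spec=spec,
                      config=NetConfig(hidden_layers=(1,)), loss_trace=[])


def _cr_record(pid, status, t0, visit_specs):
    return make_labeled(pid, status, t0, [(a, 10.0, {"creatinine": cr}) for a, cr in visit_specs])


class TestEvaluateAtT0:
    def test_perfect_separation(self, threshold_net):
        test = [
            _cr_record("c1", CKDStatus.CKD, 10.0, [(9.0, 4.0), (10.0, 4.5)]),
            _cr_record("c2", CKDStatus.CKD, 10.0, [(10.0, 3.5)]),
            _cr_record("n1", CKDStatus.NO_CKD, 8.0, [(7.5, 0.9), (8.0, 1.0)]),
        ]
        s = evaluate_at_t0(threshold_net, test, prevalence=0.3)
        assert s.sensitivity == 1.0 and s.specificity == 1.0 and s.accuracy == 1.0
        assert s.ppv == 1.0 and s.npv == 1.0

    def test_window_rule_excludes_stale_records(self, threshold_net):
        test = [
            _cr_record("c1", CKDStatus.CKD, 10.0, [(10.0, 4.0)]),
            _cr_record("c2", CKDStatus.CKD, 10.0, [(9.6, 4.0)]),  # 0.4 y before T0
            _cr_record("n1", CKDStatus.NO_CKD, 8.0, [(8.0, 1.0)]),
        ]
        s = evaluate_at_t0(threshold_net, test, t0_window_years=0.25, prevalence=0.3)
        assert s.n_pos == 1  # the stale record is not part of this evaluation

    def test_empty_eligible_set_is_an_error(self, threshold_net):
        test = [_cr_record("c1", CKDStatus.CKD, 10.0, [(9.0, 4.0)])]
        with pytest.raises(ValueError, match="near T0"):
            evaluate_at_t0(threshold_net, test, t0_window_years=0.25)


class TestHorizonEvaluation:
    def test_truncation_rule(self, threshold_net):
        # high creatinine only at the 9.8y visit: invisible at h=1
        rec = _cr_record("c1", CKDStatus.CKD, 10.0, [(8.0, 1.0), (9.8, 4.0)])
        neg = _cr_record("n1", CKDStatus.NO_CKD, 8.0, [(8.0, 1.0)])
        out = horizon_evaluation(threshold_net, [rec, neg], horizons=(0.0, 1.0), prevalence=0.3)
        assert out[0.0].sensitivity == 1.0
        assert out[1.0].sensitivity == 0.0  # only the healthy-looking 8.0y visit remains

    def test_h0_consistent_with_t0_evaluation(self, threshold_net):
        test = [
            _cr_record("c1", CKDStatus.CKD, 10.0, [(9.0, 1.0), (10.0, 4.0)]),
            _cr_record("c2", CKDStatus.CKD, 10.0, [(10.0, 1.0)]),
            _cr_record("n1", CKDStatus.NO_CKD, 8.0, [(8.0, 1.0)]),
        ]
        at_t0 = evaluate_at_t0(threshold_net, test, prevalence=0.3)
        at_h0 = horizon_evaluation(threshold_net, test, horizons=(0.0,), prevalence=0.3)[0.0]
        assert at_h0.sensitivity == at_t0.sensitivity

    def test_empty_records_dropped_or_counted(self, threshold_net):
        rec = _cr_record("c1", CKDStatus.CKD, 10.0, [(9.5, 4.0)])
        neg = _cr_record("n1", CKDStatus.NO_CKD, 8.0, [(8.0, 1.0)])
        dropped = horizon_evaluation(threshold_net, [rec, neg], horizons=(2.0,), prevalence=0.3)
        assert dropped[2.0].n_pos == 0
        counted = horizon_evaluation(
            threshold_net, [rec, neg], horizons=(2.0,), prevalence=0.3,
            count_empty_as_missed=True,
        )
        assert counted[2.0].n_pos == 1 and counted[2.0].sensitivity == 0.0

    def test_table_export(self, threshold_net):
        rec = _cr_record("c1", CKDStatus.CKD, 10.0, [(9.0, 4.0), (10.0, 4.0)])
        neg = _cr_record("n1", CKDStatus.NO_CKD, 8.0, [(8.0, 1.0)])
        out = horizon_evaluation(threshold_net, [rec, neg], horizons=(0.0, 0.5), prevalence=0.3)
        frame = summaries_to_frame(out)
        assert list(frame["horizon_years"]) == [0.0, 0.5]
        assert {"sensitivity", "specificity", "ppv", "npv"} <= set(frame.columns)


class TestStratifiedReport:
    def test_hand_tally_by_age(self, threshold_net):
        test = [
            _cr_record("c1", CKDStatus.CKD, 5.2, [(5.2, 4.0)]),   # predicted CKD
            _cr_record("c2", CKDStatus.CKD, 5.8, [(5.8, 0.5)]),   # missed
            _cr_record("c3", CKDStatus.CKD, 9.1, [(9.1, 4.0)]),
            _cr_record("n1", CKDStatus.NO_CKD, 5.5, [(5.5, 0.5)]),
            _cr_record("n2", CKDStatus.NO_CKD, 9.3, [(9.3, 4.0)]),  # false positive
        ]
        table = stratified_report(threshold_net, test, strata="age-year")
        by = {row["stratum"]: row for _, row in table.iterrows()}
        assert by[5]["sensitivity"] == pytest.approx(0.5)
        assert by[5]["specificity"] == pytest.approx(1.0)
        assert by[9]["sensitivity"] == pytest.approx(1.0)
        assert by[9]["specificity"] == pytest.approx(0.0)
        assert table["n"].sum() == len(test)

    def test_single_stratum_equals_pooled(self, threshold_net):
        test = [
            _cr_record("c1", CKDStatus.CKD, 5.2, [(5.2, 4.0)]),
            _cr_record("n1", CKDStatus.NO_CKD, 5.5, [(5.5, 0.5)]),
        ]
        table = stratified_report(threshold_net, test, strata="life-stage")
        assert len(table) == 1 and table.iloc[0]["stratum"] == "adult"

    def test_visit_count_strata_partition(self, threshold_net):
        test = [
            _cr_record("c1", CKDStatus.CKD, 6.0, [(5.0, 4.0), (6.0, 4.0)]),
            _cr_record("c2", CKDStatus.CKD, 6.0, [(6.0, 4.0)]),
        ]
        table = stratified_report(threshold_net, test, strata="visit-count")
        assert sorted(table["stratum"]) == [1, 2]
        assert table["n"].sum() == 2
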