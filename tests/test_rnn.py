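"""The recurrent classifier: forward pass, BPTT gradients, training,
feature assembly, wrapper selection and the architecture screen."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ckdpipe.ehr_core import CKDStatus
from ckdpipe.rnn import (
    FeatureSpec,
    NetConfig,
    SequenceSample,
    TrainingError,
    architecture_screen,
    build_sequences,
    count_params,
    cross_validated_f1,
    fit_feature_spec,
    forward,
    init_params,
    load_net,
    loss_and_grads,
    predict_proba,
    save_net,
    train,
    wrapper_feature_selection,
)
from ckdpipe.rnn import _forward_sample

from .conftest import make_labeled


def _gaussian_samples(rng, n, n_features=3, sep=2.0):
    out = []
    for i in range(n):
        label = i % 2
        T = int(rng.integers(2, 6))
        mu = sep if label else -sep
        out.append(SequenceSample(x=rng.normal(mu, 1.0, size=(T, n_features)), label=label))
    return out


def _spec(n_features):
    return FeatureSpec(names=tuple(f"f{i}" for i in range(n_features)), scaler={})


class TestForward:
    def test_zero_weights_give_half(self):
        widths = (3, 2)
        params = {k: np.zeros_like(v) for k, v in
                  init_params(NetConfig(hidden_layers=widths), 4, np.random.default_rng(0)).items()}
        probs, _ = _forward_sample(params, widths, np.ones((3, 4)))
        assert probs == pytest.approx([0.5, 0.5])

    def test_softmax_normalised(self):
        rng = np.random.default_rng(1)
        widths = (4, 3)
        params = init_params(NetConfig(hidden_layers=widths), 5, rng)
        for _ in range(10):
            probs, _ = _forward_sample(params, widths, rng.normal(size=(4, 5)))
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs >= 0)

    def test_hand_computed_two_step_sequence(self):
        """One feature, one unit, two time steps, hand-set weights."""
        params = {
            "W0": np.array([[0.5]]),
            "U0": np.array([[0.25]]),
            "b0": np.array([0.1]),
            "V": np.array([[1.0], [-1.0]]),
            "c": np.array([0.0, 0.0]),
        }
        x = np.array([[1.0], [-1.0]])
        h1 = math.tanh(0.5 * 1.0 + 0.1)
        h2 = math.tanh(0.5 * -1.0 + 0.25 * h1 + 0.1)
        expected = math.exp(h2) / (math.exp(h2) + math.exp(-h2))
        probs, _ = _forward_sample(params, (1,), x)
        assert probs[0] == pytest.approx(expected, abs=1e-12)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        widths = (3, 2)
        params = init_params(NetConfig(hidden_layers=widths), 4, rng)
        samples = [
            SequenceSample(x=rng.normal(size=(T, 4)), label=int(rng.integers(2)))
            for T in (1, 3, 5)
        ]
        _, grads = loss_and_grads(params, widths, samples)
        h = 1e-5
        for key, grad in grads.items():
            flat = params[key].reshape(-1)
            gflat = grad.reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h
                lp, _ = loss_and_grads(params, widths, samples)
                flat[i] = orig - h
                lm, _ = loss_and_grads(params, widths, samples)
                flat[i] = orig
                numeric = (lp - lm) / (2 * h)
                rel = abs(numeric - gflat[i]) / max(abs(numeric), abs(gflat[i]), 1e-8)
                assert rel <= 1e-4, f"{key}[{i}]: analytic {gflat[i]} vs numeric {numeric}"


class TestTraining:
    def test_separable_classes_learned(self):
        rng = np.random.default_rng(1)
        samples = _gaussian_samples(rng, 80)
        cfg = NetConfig(hidden_layers=(4,), dropout=0.0, epochs=8, seed=3, learning_rate=5e-3)
        net = train(cfg, _spec(3), samples)
        probs = predict_proba(net, samples)
        labels = np.array([s.label for s in samples])
        assert np.mean((probs >= 0.5) == labels) > 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        samples = _gaussian_samples(rng, 30)
        cfg = NetConfig(hidden_layers=(3,), epochs=2, seed=7)
        n1 = train(cfg, _spec(3), samples)
        n2 = train(cfg, _spec(3), samples)
        assert all(np.array_equal(n1.params[k], n2.params[k]) for k in n1.params)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        samples = [SequenceSample(x=rng.normal(size=(2, 3)), label=1) for _ in range(4)]
        with pytest.raises(TrainingError):
            train(NetConfig(hidden_layers=(3,)), _spec(3), samples)

    def test_loss_trace_length(self):
        rng = np.random.default_rng(4)
        net = train(NetConfig(hidden_layers=(3,), epochs=5, seed=0), _spec(3),
                    _gaussian_samples(rng, 20))
        assert len(net.loss_trace) == 5


class TestBuildSequences:
    def test_standardisation_and_order(self, catalog):
        rec = make_labeled(
            "p", CKDStatus.CKD, 9.0,
            [(float(a), 10.0, {"creatinine": 2.0}) for a in (5, 6, 7, 8, 9)],
        )
        spec = FeatureSpec(
            names=("creatinine", "age"),
            scaler={"creatinine": (2.0, 1.0), "age": (7.0, 2.0)},
        )
        (sample,) = build_sequences([rec], spec)
        assert sample.x.shape == (5, 2)
        assert np.allclose(sample.x[:, 0], 0.0)  # equal to scaler mean
        assert sample.x[0, 1] == pytest.approx(-1.0)  # (5-7)/2

    def test_weight_carry_forward(self):
        rec = make_labeled(
            "p", CKDStatus.NO_CKD, 7.0,
            [(5.0, 12.0, {}), (6.0, None, {}), (7.0, None, {})],
        )
        spec = FeatureSpec(names=("weight",), scaler={"weight": (0.0, 1.0)}, weight_fallback=9.0)
        (sample,) = build_sequences([rec], spec)
        assert list(sample.x[:, 0]) == [12.0, 12.0, 12.0]
        # no prior observation: the cohort fallback is used
        rec2 = make_labeled("q", CKDStatus.NO_CKD, 7.0, [(5.0, None, {})])
        (s2,) = build_sequences([rec2], spec)
        assert s2.x[0, 0] == 9.0

    def test_probable_records_refused(self):
        rec = make_labeled("p", CKDStatus.PROBABLE_CKD, None, [(5.0,)])
        spec = FeatureSpec(names=("age",), scaler={"age": (5.0, 1.0)})
        with pytest.raises(ValueError, match="PROBABLE"):
            build_sequences([rec], spec)

    def test_fit_feature_spec_scaler(self):
        recs = [
            make_labeled("p", CKDStatus.CKD, 6.0, [(5.0, 10.0, {"creatinine": 1.0}),
                                                   (6.0, 14.0, {"creatinine": 3.0})])
        ]
        spec = fit_feature_spec(recs, ("creatinine", "weight", "age"))
        assert spec.scaler["creatinine"][0] == pytest.approx(2.0)
        assert spec.weight_fallback == pytest.approx(12.0)


class TestModelSelection:
    def _builder(self, rng, n=90):
        # weakly informative features (class means +-1, SD 2) so that each
        # additional genuine feature still improves the CV score
        base = []
        for i in range(n):
            label = i % 2
            T = int(rng.integers(2, 6))
            mu = 1.0 if label else -1.0
            base.append(SequenceSample(x=rng.normal(mu, 2.0, size=(T, 2)), label=label))
        noise = rng.normal(size=(n, 10, 1))

        def build(names):
            out = []
            for i, s in enumerate(base):
                cols = []
                for name in names:
                    if name == "noise":
                        cols.append(noise[i, : s.x.shape[0]])
                    else:
                        cols.append(s.x[:, [int(name[1])]])
                out.append(SequenceSample(x=np.hstack(cols), label=s.label))
            return out

        return build

    def test_forward_selection_is_nested_and_noise_last(self):
        rng = np.random.default_rng(5)
        build = self._builder(rng)
        cfg = NetConfig(hidden_layers=(3, 7), epochs=5, dropout=0.0, seed=2, learning_rate=1e-2)
        trace = wrapper_feature_selection(["f0", "f1", "noise"], build, folds=3, base_config=cfg)
        forward_sets = [set(subset) for subset, _ in trace["forward"]]
        for small, large in zip(forward_sets, forward_sets[1:]):
            assert small < large
        assert trace["forward"][-1][0][-1] == "noise"
        # backward: the full set is scored first, then features are removed
        assert set(trace["backward"][0][0]) == {"f0", "f1", "noise"}
        assert len(trace["backward"][-1][0]) == 1

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="2 candidate"):
            wrapper_feature_selection(["only"], lambda names: [], folds=3)

    def test_folds_exceeding_class_count_rejected(self):
        rng = np.random.default_rng(6)
        samples = _gaussian_samples(rng, 4)
        with pytest.raises(ValueError, match="folds"):
            cross_validated_f1(NetConfig(hidden_layers=(2,), epochs=1), samples, folds=5)

    def test_architecture_screen_single_and_tie(self):
        rng = np.random.default_rng(7)
        samples = _gaussian_samples(rng, 60, sep=3.0)
        lone = NetConfig(hidden_layers=(3,), epochs=3, dropout=0.0, seed=0, learning_rate=5e-3)
        best, table = architecture_screen([lone], samples, folds=3)
        assert best is lone and len(table) == 1
        big = NetConfig(hidden_layers=(10, 10), epochs=3, dropout=0.0, seed=0, learning_rate=5e-3)
        best2, table2 = architecture_screen([big, lone], samples, folds=3)
        assert len(table2) == 2
        f1s = table2["mean_cv_f1"]
        if f1s.iloc[0] == f1s.iloc[1]:
            assert best2 is lone  # tie broken toward fewer parameters
        else:
            assert best2 is (big if f1s.iloc[0] > f1s.iloc[1] else lone)

    def test_count_params(self):
        cfg = NetConfig(hidden_layers=(2,))
        # W: 2x3, U: 2x2, b: 2, V: 2x2, c: 2 -> 6+4+2+4+2
        assert count_params(cfg, 3) == 18


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    samples = _gaussian_samples(rng, 20)
    cfg = NetConfig(hidden_layers=(3,), epochs=1, seed=2)
    net = train(cfg, _spec(3), samples)
    path = save_net(net, tmp_path / "model.json")
    loaded = load_net(path)
    assert all(np.array_equal(net.params[k], loaded.params[k]) for k in net.params)
    assert loaded.feature_spec.names == net.feature_spec.names
    x = samples[0]
    assert forward(loaded, x) == pytest.approx(forward(net, x))
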