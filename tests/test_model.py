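"""The stacked-LSTM identifier: parameter accounting, gradients, training."""

import itertools

import numpy as np
import pytest

import gaitid as g
from gaitid.errors import ConfigurationError, DomainError
from gaitid.nn import softmax_cross_entropy

EXPECTED_PARAMS = {
    "ID1": 91_355,
    "ID2": 87_875,
    "ID3": 96_365,
    "ID4": 89_255,
    "ID5": 141_755,
}


def toy_windows(rng, n, K=3, T=8, F=1):
    return g.WindowSet(rng.normal(size=(n, T, F)), rng.integers(0, K, size=n),
                       tuple(f"u{i}" for i in range(K)),
                       ("vertical_acceleration",) * F, T, T // 2)


class TestParameterCounts:
    @pytest.mark.parametrize("name", sorted(EXPECTED_PARAMS))
    def test_analytic_count_matches_built_model(self, name):
        config = g.PRESETS[name]
        analytic = g.count_trainable_params(config)
        model, manifest = g.build_architecture(config)
        assert analytic == EXPECTED_PARAMS[name]
        assert model.n_trainable_params() == analytic
        assert sum(e["n_params"] for e in manifest) == analytic

    def test_toy_config_hand_sum(self):
        # LSTM(1→1): 4·(1·2+1)=12, twice; dense 1→1: 2 → 26 total
        config = g.ArchConfig(window_len=4, n_features=1, lstm_units=(1, 1),
                              dense_units=(), n_classes=1)
        assert g.count_trainable_params(config) == 26

    def test_count_is_independent_of_window_len(self):
        a = g.preset("ID5")
        b = g.preset("ID5", window_len=300)
        assert g.count_trainable_params(a) == g.count_trainable_params(b)


class TestArchitecture:
    def test_id5_manifest_layout(self):
        model, manifest = g.build_architecture(g.PRESETS["ID5"])
        kinds = [e["kind"] for e in manifest]
        assert kinds == ["lstm", "lstm", "dense_relu", "dense_relu", "dense_softmax"]
        assert manifest[0]["return_sequences"] is True
        assert manifest[1]["return_sequences"] is False
        assert manifest[-1]["output_width"] == 15

    def test_two_feature_variant_changes_only_first_layer(self):
        one, _ = g.build_architecture(g.preset("ID5"))
        two, manifest = g.build_architecture(g.preset("ID5", n_features=2))
        assert manifest[0]["input_width"] == 2
        # downstream widths unchanged
        assert [e["output_width"] for e in manifest] == \
            [e["output_width"] for e in one.layer_manifest()]

    def test_single_class_softmax_is_constant_one(self, rng):
        config = g.ArchConfig(window_len=6, lstm_units=(2, 2), dense_units=(3,),
                              n_classes=1)
        model = g.GaitClassifier(config, seed=0)
        ws = toy_windows(rng, 5, K=1, T=6)
        probs = model.predict_proba(ws)
        assert np.allclose(probs, 1.0)
        assert np.array_equal(model.identify(ws), np.zeros(5))

    def test_exactly_two_lstm_layers_enforced(self):
        with pytest.raises(DomainError):
            g.ArchConfig(lstm_units=(10,))


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, rng):
        """Central-difference check of the full stack (float64)."""
        config = g.ArchConfig(window_len=5, n_features=2, lstm_units=(3, 4),
                              dense_units=(5,), n_classes=3)
        model = g.GaitClassifier(config, seed=1, dtype=np.float64)
        X = rng.normal(size=(4, 5, 2))
        Y = np.eye(3)[rng.integers(0, 3, size=4)]

        logits = model._forward(X, cache=True)
        _, _, dlogits = softmax_cross_entropy(logits, Y)
        model._backward(dlogits)

        def loss():
            return softmax_cross_entropy(model._forward(X, cache=False), Y)[0]

        for layer in model.layers:
            for p, grad in zip(layer.params, layer.grads):
                for idx in itertools.islice(np.ndindex(p.shape), 8):
                    eps, old = 1e-6, p[idx]
                    p[idx] = old + eps
                    up = loss()
                    p[idx] = old - eps
                    down = loss()
                    p[idx] = old
                    numeric = (up - down) / (2 * eps)
                    assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestInference:
    def test_probability_rows_sum_to_one(self, rng):
        model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                              dense_units=(6,), n_classes=5))
        ws = toy_windows(rng, 20, K=5)
        probs = model.predict_proba(ws)
        assert probs.shape == (20, 5)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_equals_single_window_prediction(self, rng):
        model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                              dense_units=(6,), n_classes=5))
        ws = toy_windows(rng, 10, K=5)
        batch = model.predict_proba(ws)
        singles = np.vstack([model.predict_proba(ws.subset(np.array([i])))
                             for i in range(10)])
        assert np.allclose(batch, singles, atol=1e-6)

    def test_identify_is_argmax_of_probabilities(self, rng):
        model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                              dense_units=(6,), n_classes=5))
        ws = toy_windows(rng, 15, K=5)
        assert np.array_equal(model.identify(ws),
                              model.predict_proba(ws).argmax(axis=1))

    def test_shape_mismatch_rejected(self, rng):
        model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                              dense_units=(6,), n_classes=5))
        with pytest.raises(ConfigurationError):
            model.predict_proba(toy_windows(rng, 3, K=5, T=9))


class TestTraining:
    def test_history_bookkeeping_one_epoch(self, rng):
        ws = toy_windows(rng, 64, K=3)
        model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                              dense_units=(6,), n_classes=3))
        fit = g.train_model(model, ws, config=g.TrainConfig(epochs=1, batch_size=16))
        assert all(len(v) == 1 for v in fit.history.values())

    def test_same_seed_reproduces_history(self, rng):
        ws = toy_windows(rng, 48, K=3)
        cfg = g.TrainConfig(epochs=3, batch_size=16, seed=7)
        hists = []
        for _ in range(2):
            model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                                  dense_units=(6,), n_classes=3),
                                     seed=7)
            hists.append(g.train_model(model, ws, config=cfg).history)
        assert hists[0] == hists[1]

    def test_batch_size_larger_than_train_set_rejected(self, rng):
        ws = toy_windows(rng, 20, K=3)
        model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                              dense_units=(6,), n_classes=3))
        with pytest.raises(ConfigurationError):
            g.train_model(model, ws, config=g.TrainConfig(epochs=1, batch_size=64))

    def test_separable_cohort_learns(self, small_windows):
        """Well-separated step frequencies: loss descends and training
        accuracy becomes much better than chance within a few epochs."""
        split = g.split_train_test(small_windows, 0.3, seed=5)
        arch = g.preset("ID1", n_classes=small_windows.n_classes)
        model = g.GaitClassifier(
            arch, seed=5,
            input_shift=g.default_input_shift(small_windows.feature_names))
        fit = g.train_model(model, split.train,
                            config=g.TrainConfig(epochs=10, batch_size=16, seed=5))
        assert fit.history["loss"][-1] < fit.history["loss"][0]
        assert fit.history["accuracy"][-1] > 0.9
        report = g.evaluate_model(fit.model, split.test)
        # well above chance (a 5x multiple would exceed 1.0 for K=3)
        assert report.accuracy >= min(0.9, 5 / small_windows.n_classes)

    def test_save_load_round_trip(self, rng, tmp_path):
        ws = toy_windows(rng, 12, K=3)
        model = g.GaitClassifier(g.ArchConfig(window_len=8, lstm_units=(4, 4),
                                              dense_units=(6,), n_classes=3),
                                 input_shift=(9.81,))
        model.save(tmp_path / "run")
        back = g.GaitClassifier.load(tmp_path / "run")
        assert np.allclose(back.predict_proba(ws), model.predict_proba(ws))
        assert np.allclose(back.input_shift, model.input_shift)
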