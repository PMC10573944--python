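"""The seven-class sequential classifier: construction, training, evaluation."""

from __future__ import annotations

import numpy as np
import pytest

from selectscreen.activity_nn import (
    ActivityClassifier,
    NNModelSpec,
    categorical_cross_entropy,
    evaluate_predictions,
)

BITS = 128


def small_spec(**kw) -> NNModelSpec:
    defaults = dict(input_width=BITS, hidden_layers=(32,), epochs=5, seed=0)
    defaults.update(kw)
    return NNModelSpec(**defaults)


def random_inputs(n, seed=0):
    rng = np.random.default_rng(seed)
    return (rng.random((n, BITS)) < 0.1).astype(np.uint8)


class TestBuild:
    def test_topology_echoes_spec(self):
        model = ActivityClassifier.build(small_spec(hidden_layers=(512, 128),
                                                    input_width=2048))
        shapes = [w.shape for w in model.weights]
        assert shapes == [(2048, 512), (512, 128), (128, 7)]

    def test_untrained_predictions_are_distributions(self):
        model = ActivityClassifier.build(small_spec())
        proba = model.predict_proba(random_inputs(10))
        assert proba.shape == (10, 7)
        assert (proba >= 0).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_initial_predictions(self):
        X = random_inputs(5)
        a = ActivityClassifier.build(small_spec(seed=7)).predict_proba(X)
        b = ActivityClassifier.build(small_spec(seed=7)).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [dict(epochs=0), dict(hidden_layers=(0,)),
                                     dict(input_width=0), dict(output_classes=5)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            small_spec(**bad)


class TestTrain:
    def test_empty_training_set_rejected(self):
        model = ActivityClassifier.build(small_spec())
        with pytest.raises(ValueError):
            model.train(np.zeros((0, BITS)), [])

    def test_class_outside_range_rejected(self):
        model = ActivityClassifier.build(small_spec())
        with pytest.raises(ValueError):
            model.train(random_inputs(3), [1, 8, 2])

    def test_one_epoch_appends_one_history_entry(self):
        model = ActivityClassifier.build(small_spec(epochs=1))
        model.train(random_inputs(20), [1] * 20)
        assert len(model.history["loss"]) == 1
        assert len(model.history["accuracy"]) == 1

    def test_single_class_degenerate_fit(self):
        X = random_inputs(40, seed=3)
        model = ActivityClassifier.build(small_spec(epochs=30, seed=3))
        model.train(X, [4] * 40)
        assert (model.predict_class(X) == 4).all()
        assert model.evaluate(X, [4] * 40).accuracy == 1.0

    def test_untrained_accuracy_near_chance_on_random_labels(self):
        # balanced random labels: accuracy ~ Binomial(n, 1/7)
        n = 700
        rng = np.random.default_rng(5)
        y = rng.permutation(np.repeat(np.arange(1, 8), n // 7))
        model = ActivityClassifier.build(small_spec(seed=5))
        acc = model.evaluate(random_inputs(n, seed=6), y).accuracy
        p = 1 / 7
        half_width = 4 * np.sqrt(p * (1 - p) / n)
        assert abs(acc - p) < half_width

    def test_training_reduces_loss(self, tiny_features):
        X, y = tiny_features
        spec = NNModelSpec(input_width=X.shape[1], hidden_layers=(64,),
                           epochs=20, seed=1)
        model = ActivityClassifier.build(spec).train(X, y)
        assert model.history["loss"][-1] < model.history["loss"][0]

    def test_same_seed_training_is_bit_reproducible(self):
        X = random_inputs(60, seed=2)
        y = (np.arange(60) % 7) + 1
        runs = []
        for _ in range(2):
            m = ActivityClassifier.build(small_spec(epochs=4, seed=9))
            m.train(X, y)
            runs.append(m)
        for wa, wb in zip(runs[0].weights, runs[1].weights):
            np.testing.assert_array_equal(wa, wb)
        assert runs[0].history == runs[1].history


class TestPredict:
    def test_empty_input_gives_empty_output(self):
        model = ActivityClassifier.build(small_spec())
        assert model.predict_proba(np.zeros((0, BITS))).shape == (0, 7)

    def test_duplicated_row_duplicated_output(self):
        model = ActivityClassifier.build(small_spec())
        X = random_inputs(1)
        proba = model.predict_proba(np.vstack([X, X]))
        np.testing.assert_array_equal(proba[0], proba[1])

    def test_width_mismatch_rejected(self):
        model = ActivityClassifier.build(small_spec())
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((3, BITS + 1)))


class TestEvaluate:
    def test_perfect_one_hot_predictions(self):
        y = np.array([1, 3, 7, 4])
        proba = np.zeros((4, 7))
        proba[np.arange(4), y - 1] = 1.0
        res = evaluate_predictions(proba, y)
        assert res.accuracy == 1.0
        assert res.loss == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictor_loss_is_ln7(self):
        proba = np.full((50, 7), 1 / 7)
        y = (np.arange(50) % 7) + 1
        res = evaluate_predictions(proba, y)
        assert res.loss == pytest.approx(np.log(7), rel=1e-12)

    def test_toy_hand_computed_loss(self):
        # five samples with hand-set probabilities on the true class
        p_true = np.array([0.5, 0.25, 0.1, 0.9, 1 / 7])
        y = np.array([1, 2, 3, 4, 5])
        proba = np.full((5, 7), 1e-3)
        proba[np.arange(5), y - 1] = p_true
        proba /= proba.sum(axis=1, keepdims=True)
        expected = -np.mean(np.log(proba[np.arange(5), y - 1]))
        res = evaluate_predictions(proba, y)
        assert res.loss == pytest.approx(expected, rel=1e-12)

    def test_confusion_consistent_with_accuracy(self, tiny_model, tiny_features):
        X, y = tiny_features
        res = tiny_model.evaluate(X, y)
        assert res.confusion.sum() == len(y)
        assert res.accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum()
        )

    def test_empty_validation_set_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.evaluate(np.zeros((0, 256)), [])

    def test_argmax_tie_goes_to_lower_class(self):
        proba = np.zeros((1, 7))
        proba[0, [1, 4]] = 0.5
        assert np.argmax(proba, axis=1)[0] + 1 == 2


class TestCrossEntropyHelper:
    def test_matches_manual_formula(self):
        rng = np.random.default_rng(0)
        proba = rng.dirichlet(np.ones(7), size=10)
        y = rng.integers(1, 8, size=10)
        manual = -np.mean([np.log(proba[i, y[i] - 1]) for i in range(10)])
        assert categorical_cross_entropy(proba, y) == pytest.approx(manual)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_model, tiny_features):
        X, _ = tiny_features
        tiny_model.save(tmp_path / "model")
        back = ActivityClassifier.load(tmp_path / "model")
        np.testing.assert_array_equal(
            tiny_model.predict_proba(X[:10]), back.predict_proba(X[:10])
        )
        assert back.spec == tiny_model.spec
        assert back.history["loss"] == pytest.approx(tiny_model.history["loss"])


def test_label_recovery_cross_checked_with_sklearn(tiny_features):
    """Both our classifier and an independent sklearn MLP learn the tiny
    synthetic structure-activity map far above the 1/7 chance level."""
    from sklearn.neural_network import MLPClassifier

    X, y = tiny_features
    ours = ActivityClassifier.build(
        NNModelSpec(input_width=X.shape[1], hidden_layers=(64, 32),
                    epochs=40, seed=0)
    ).train(X, y)
    ours_acc = ours.evaluate(X, y).accuracy

    ref = MLPClassifier(hidden_layer_sizes=(64, 32), max_iter=400,
                        random_state=0).fit(X, y)
    ref_acc = ref.score(X, y)
    assert ours_acc > 0.5
    assert ref_acc > 0.5
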