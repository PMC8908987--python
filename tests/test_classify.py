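import numpy as np
import pytest

from lungcad.classify import (
    EvalReport,
    FusionClassifier,
    StackedAutoencoderClassifier,
    build_stacked_sae,
    evaluate,
    fuse,
    split_train_test,
    stacked_layer_dims,
    train_descriptor_classifier,
)


def toy_set(n=40, sep=2.0, seed=0, d=2):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, d)), rng.normal(sep, 0.3, (n // 2, d))])
    y = np.array(["benign"] * (n // 2) + ["malignant"] * (n // 2))
    return X, y


class TestArchitecture:
    def test_one_third_reduction_dims(self):
        assert stacked_layer_dims(200) == (134, 90, 60)
        assert build_stacked_sae(200).layer_dims == (134, 90, 60)

    def test_minimum_width_guard(self):
        assert stacked_layer_dims(3) == (2, 2, 2)

    def test_reduce_to_one_third_variant(self):
        assert stacked_layer_dims(90, rule="one_third") == (30, 10, 4)

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError):
            build_stacked_sae(2)


class TestStackedClassifier:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = toy_set()
        clf = StackedAutoencoderClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_probabilities_sum_to_one(self):
        X, y = toy_set(seed=1)
        clf = StackedAutoencoderClassifier(random_state=0).fit(X, y)
        np.testing.assert_allclose(clf.predict_proba(X).sum(axis=1), 1.0, atol=1e-6)

    def test_zero_variance_features_give_class_prior(self):
        X = np.ones((30, 5))
        y = np.array(["benign"] * 10 + ["malignant"] * 20)
        clf = StackedAutoencoderClassifier(random_state=0).fit(X, y)
        p = clf.malignancy_probability(X)
        np.testing.assert_allclose(p, 2.0 / 3.0, atol=0.02)

    def test_training_is_bitwise_deterministic(self):
        X, y = toy_set(seed=2)
        p1 = StackedAutoencoderClassifier(random_state=7).fit(X, y).predict_proba(X)
        p2 = StackedAutoencoderClassifier(random_state=7).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            StackedAutoencoderClassifier().fit(X, np.array(["benign"] * 10))

    def test_sklearn_get_set_params_roundtrip(self):
        clf = StackedAutoencoderClassifier(pretrain_epochs=10)
        params = clf.get_params()
        clone = StackedAutoencoderClassifier().set_params(**params)
        assert clone.get_params() == params

    def test_train_descriptor_classifier_wrapper(self):
        X, y = toy_set(seed=3, d=10)
        cfg = build_stacked_sae(10, seed=0, pretrain_epochs=50, finetune_epochs=50)
        model, probs = train_descriptor_classifier(X, y, cfg)
        assert probs.shape == (40,)
        assert np.all((probs >= 0) & (probs <= 1))


class TestFusion:
    def test_perfect_probabilities_reproduce_labels(self):
        rng = np.random.default_rng(0)
        y = np.array(["benign"] * 30 + ["malignant"] * 30)
        P = np.tile((y == "malignant").astype(float)[:, None], (1, 6))
        P += rng.normal(0, 0.01, P.shape)
        probs, model = fuse(np.clip(P, 0, 1), y, seed=0)
        assert (((probs >= 0.5) == (y == "malignant"))).mean() == 1.0
        assert np.all((probs >= 0) & (probs <= 1))

    def test_wrong_input_dimension_raises(self):
        y = np.array(["benign"] * 5 + ["malignant"] * 5)
        with pytest.raises(ValueError):
            fuse(np.zeros((10, 4)), y, seed=0)

    def test_one_informative_plus_noise_keeps_accuracy(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.array(["benign"] * (n // 2) + ["malignant"] * (n // 2))
        informative = np.concatenate([rng.uniform(0, 0.25, n // 2),
                                      rng.uniform(0.75, 1, n // 2)])
        P = np.column_stack([informative] + [rng.uniform(0, 1, n) for _ in range(5)])
        probs, _ = fuse(P, y, seed=0)
        acc = (((probs >= 0.5) == (y == "malignant"))).mean()
        informative_alone = (((informative >= 0.5) == (y == "malignant"))).mean()
        assert acc >= informative_alone - 0.02


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1] * 5 + [0] * 5)
        p = y.astype(float)
        rep = evaluate(p, y)
        assert rep.accuracy == rep.sensitivity == rep.specificity == rep.precision == 100.0
        assert rep.auc == 1.0

    def test_inverted_predictions_auc_zero(self):
        y = np.array([1] * 5 + [0] * 5)
        rep = evaluate(1.0 - y, y)
        assert rep.auc == 0.0

    def test_hand_computed_confusion(self):
        # TP 9, FN 1, TN 8, FP 2
        y = np.array([1] * 10 + [0] * 10)
        p = np.array([0.9] * 9 + [0.1] + [0.2] * 8 + [0.8, 0.7])
        rep = evaluate(p, y)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (9, 1, 8, 2)
        assert rep.sensitivity == 90.0 and rep.specificity == 80.0
        assert rep.accuracy == 85.0
        assert rep.precision == pytest.approx(81.818, abs=0.01)

    def test_metrics_recompute_from_counts(self):
        y = np.array([1] * 7 + [0] * 13)
        p = np.random.default_rng(3).uniform(size=20)
        rep = evaluate(p, y)
        assert rep.accuracy == pytest.approx(100 * (rep.tp + rep.tn) / 20)

    def test_string_labels(self):
        y = np.array(["malignant"] * 3 + ["benign"] * 3)
        rep = evaluate(np.array([0.9, 0.8, 0.7, 0.1, 0.2, 0.3]), y)
        assert rep.accuracy == 100.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))


class TestSplit:
    def test_fraction_and_stratification(self):
        class R:
            def __init__(self, label):
                self.label = label

        records = [R("benign")] * 100 + [R("malignant")] * 100
        train, test = split_train_test(records, 0.70, seed=0)
        assert len(train) == 140 and len(test) == 60
        assert sum(r.label == "malignant" for r in train) == 70

    def test_reproducible(self):
        class R:
            def __init__(self, i, label):
                self.i, self.label = i, label

        records = [R(i, "benign" if i % 2 else "malignant") for i in range(30)]
        a1, _ = split_train_test(records, seed=5)
        a2, _ = split_train_test(records, seed=5)
        assert [r.i for r in a1] == [r.i for r in a2]
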