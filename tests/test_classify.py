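"""LSSVM, MLP, the seven metrics and cross-validated evaluation."""

import math

import numpy as np
import pytest

from polypfeat import classify
from polypfeat.classify import ClassifierSpec, ConfusionCounts, LSSVM
from polypfeat.errors import InvalidInputError


def blobs(rng, n=40, sep=6.0):
    X = np.vstack(
        [rng.normal(0, 1, (n // 2, 2)), rng.normal(sep, 1, (n // 2, 2))]
    )
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestLSSVM:
    def test_separable_blobs_training_accuracy(self):
        X, y = blobs(np.random.default_rng(0))
        model = LSSVM(gamma=10.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_kkt_residual_small(self):
        X, y = blobs(np.random.default_rng(1))
        model = LSSVM(gamma=10.0).fit(X, y)
        t = np.where(y == 1, 1.0, -1.0)
        K = model._kernel(X, X)
        resid = K @ model.coef_ + model.coef_ / model.gamma + model.bias_ - t
        assert np.abs(resid).max() < 1e-8
        assert abs(model.coef_.sum()) < 1e-8  # equality constraint

    def test_two_point_problem(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([0, 1])
        model = LSSVM(gamma=100.0, gamma_k=0.5).fit(X, y)
        assert list(model.predict(X)) == [0, 1]
        # midpoint of the two points lies on the decision boundary
        assert abs(model.decision_function([[1.0, 0.0]])[0]) < 1e-9

    def test_one_class_rejected(self):
        X = np.random.default_rng(2).normal(size=(8, 2))
        with pytest.raises(InvalidInputError):
            LSSVM().fit(X, np.zeros(8))

    def test_tuned_matches_agreement_with_reference_svm(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(3)
        X, y = blobs(rng, n=60, sep=2.5)
        model = classify.train_lssvm(X, y, seed=0)
        ref = SVC(kernel="rbf").fit(X, y)
        agree = np.mean(model.predict(X) == ref.predict(X))
        assert agree >= 0.9


class TestMLP:
    def test_xor_capacity(self):
        rng = np.random.default_rng(0)
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        X = np.vstack([base + rng.normal(0, 0.05, (4, 2)) for _ in range(20)])
        y = np.tile([0, 1, 1, 0], 20)
        model = classify.train_mlp(X, y, hidden_spec=(8,), seed=0)
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng, n=30, sep=2.0)
        p1 = classify.train_mlp(X, y, seed=7).predict(X)
        p2 = classify.train_mlp(X, y, seed=7).predict(X)
        assert np.array_equal(p1, p2)

    def test_empty_hidden_spec_rejected(self):
        X, y = blobs(np.random.default_rng(2))
        with pytest.raises(InvalidInputError):
            classify.train_mlp(X, y, hidden_spec=())

    def test_default_hidden_size(self):
        assert classify.default_hidden_size(102, 2) == 52
        assert classify.default_hidden_size(36, 2) == 19


class TestMetrics:
    def test_worked_example(self):
        m = classify.metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["g_mean"] == pytest.approx(math.sqrt(0.72), abs=1e-4)
        assert m["recall"] == m["sensitivity"]
        p, r = m["precision"], m["recall"]
        assert m["f_measure"] == pytest.approx(2 * p * r / (p + r))

    def test_perfect_prediction(self):
        m = classify.metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in classify.METRIC_NAMES)

    def test_degenerate_zero_denominators_flagged(self):
        m = classify.metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m["precision"] == 0.0
        assert m["sensitivity"] == 0.0
        assert "precision" in m["undefined"]

    def test_accuracy_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            m = classify.metrics(c)
            n_pos, n_neg = c.tp + c.fn, c.tn + c.fp
            if n_pos and n_neg:
                expected = (m["sensitivity"] * n_pos + m["specificity"] * n_neg) / c.total
                assert m["accuracy"] == pytest.approx(expected)


class TestCrossValidate:
    def test_five_stratified_folds_partition_data(self):
        rng = np.random.default_rng(0)
        X, y = blobs(rng, n=50, sep=4.0)
        rep = classify.cross_validate(X, y, ClassifierSpec("lssvm", {"gamma": 10.0}))
        assert len(rep.per_fold) == 5
        assert sorted(np.unique(rep.fold_assignment)) == [0, 1, 2, 3, 4]
        for fold in range(5):
            members = rep.fold_assignment == fold
            assert abs(members.sum() - 10) <= 1
            assert abs(y[members].sum() - 5) <= 1  # stratified

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng, n=40, sep=2.0)
        a = classify.cross_validate(X, y, ClassifierSpec("lssvm", {"gamma": 1.0}), seed=3)
        b = classify.cross_validate(X, y, ClassifierSpec("lssvm", {"gamma": 1.0}), seed=3)
        assert a.per_fold.equals(b.per_fold)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_label_permutation_gives_chance_accuracy(self):
        rng = np.random.default_rng(2)
        X, y = blobs(rng, n=100, sep=4.0)
        y_perm = rng.permutation(y)
        rep = classify.cross_validate(
            X, y_perm, ClassifierSpec("lssvm", {"gamma": 10.0}), seed=0
        )
        # binomial 99.7% interval around 0.5 at n = 100
        assert 0.35 <= rep.mean["accuracy"] <= 0.65

    def test_too_small_class_rejected(self):
        X = np.random.default_rng(3).normal(size=(8, 2))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(InvalidInputError):
            classify.cross_validate(X, y, n_folds=5)

    def test_report_text_mentions_all_metrics(self):
        rng = np.random.default_rng(4)
        X, y = blobs(rng, n=40)
        rep = classify.cross_validate(X, y, ClassifierSpec("lssvm", {"gamma": 10.0}))
        text = rep.to_text()
        for m in classify.METRIC_NAMES:
            assert m in text
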