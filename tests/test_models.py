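"""Classifiers, fold plans, metrics panel, ROC/PR curves."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from lungsound.features import FeatureMatrix
from lungsound.models import (
    NNNConfig,
    classification_metrics,
    f1_from_precision_recall,
    participant_folds,
    positive_scores,
    roc_pr_curves,
    run_cv,
    train_narrow_nn,
    train_quadratic_svm,
)


class TestParticipantFolds:
    def _participants(self, n_per_class):
        out = {f"A{i}": 1 for i in range(n_per_class)}
        out.update({f"H{i}": 2 for i in range(n_per_class)})
        return out

    def test_default_design_fold_sizes(self):
        plan = participant_folds(self._participants(60), 10, seed=0)
        folds = np.array(list(plan.assignment.values()))
        for f in range(10):
            assert np.sum(folds == f) == 12  # 12 participants = 360 segments

    def test_stratified_within_one(self):
        mapping = self._participants(13)
        plan = participant_folds(mapping, 10, seed=1)
        for label in (1, 2):
            counts = np.bincount(
                [plan.assignment[p] for p, l in mapping.items() if l == label],
                minlength=10,
            )
            assert counts.max() - counts.min() <= 1

    def test_leave_one_participant_out(self):
        mapping = self._participants(5)
        plan = participant_folds(mapping, 5, seed=0)
        folds = list(plan.assignment.values())
        assert sorted(set(folds)) == list(range(5))

    def test_same_seed_identical_plan(self):
        m = self._participants(12)
        p1 = participant_folds(m, 10, seed=3)
        p2 = participant_folds(m, 10, seed=3)
        assert p1.assignment == p2.assignment

    def test_too_few_participants_errors(self):
        with pytest.raises(ValueError, match="fewer"):
            participant_folds(self._participants(5), 10)

    def test_partition_law(self):
        mapping = self._participants(12)
        plan = participant_folds(mapping, 10, seed=0)
        pids = np.repeat(sorted(mapping), 30)  # 30 segments each
        folds = plan.fold_indices(pids)
        test_total = sum(len(te) for _, te in folds)
        assert test_total == len(pids)
        seen = np.concatenate([te for _, te in folds])
        assert len(np.unique(seen)) == len(pids)


def _xor_points():
    X = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
    y = np.array([1, 1, 2, 2])
    return X, y


class TestQuadraticSVM:
    def test_xor_separable_under_quadratic_kernel(self):
        X, y = _xor_points()
        model = train_quadratic_svm(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_label_swap_flips_decision_sign(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(30) > 0, 1, 2)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        m1 = train_quadratic_svm(X, y)
        m2 = train_quadratic_svm(X, np.where(y == 1, 2, 1))
        # symmetry up to the SVC solver's convergence tolerance
        np.testing.assert_allclose(
            m1.decision_function(X), -m2.decision_function(X), atol=5e-3
        )

    def test_linearly_separable_zero_training_errors(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.repeat([1, 2], 20)
        model = train_quadratic_svm(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_single_class_errors(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            train_quadratic_svm(X, np.ones(5, dtype=int))

    def test_decision_values_match_dual_evaluation(self):
        # independent oracle: explicit kernel matrix + dual coefficients
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = np.where(X[:, 0] + X[:, 1] ** 2 > 0.5, 1, 2)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        model = train_quadratic_svm(X, y)
        Z = rng.standard_normal((10, 4))
        K = (1.0 + Z @ model.support_vectors_.T) ** 2
        manual = K @ model.dual_coef_.ravel() + model.intercept_[0]
        np.testing.assert_allclose(model.decision_function(Z), manual, atol=1e-6)


class TestNarrowNN:
    def _toy(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([1, 2], n // 2)
        X = rng.standard_normal((n, 2)) + np.where(y == 1, 2.0, -2.0)[:, None]
        return X, y

    def test_separable_toy_training_accuracy(self):
        X, y = self._toy()
        model = train_narrow_nn(X, y, NNNConfig(seed=0))
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_same_seed_identical_weights(self):
        X, y = self._toy()
        m1 = train_narrow_nn(X, y, NNNConfig(seed=7))
        m2 = train_narrow_nn(X, y, NNNConfig(seed=7))
        for w1, w2 in zip(m1.coefs_, m2.coefs_):
            np.testing.assert_array_equal(w1, w2)

    def test_constant_zero_input_constant_predictions(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1, 2], 50)
        model = train_narrow_nn(np.zeros((100, 3)), y, NNNConfig(seed=0))
        preds = model.predict(rng.standard_normal((20, 3)) * 0.0)
        assert len(np.unique(preds)) == 1

    def test_architecture(self):
        X, y = self._toy(n=100)
        model = train_narrow_nn(X, y, NNNConfig(seed=0))
        assert model.hidden_layer_sizes == (10,)
        assert len(model.coefs_) == 2  # one hidden layer


def _toy_matrix(n=120, sep=5.0, seed=0, n_participants=12):
    """FeatureMatrix with n rows over n_participants, class gap ``sep``."""
    rng = np.random.default_rng(seed)
    per = n // n_participants
    pids = np.repeat([f"P{i:02d}" for i in range(n_participants)], per)
    labels = np.repeat([1, 2], n // 2)
    X = rng.standard_normal((n, 4))
    X[:, 0] += np.where(labels == 1, sep, -sep)
    meta = pd.DataFrame(
        {"participant_id": pids, "label": labels, "site_id": "s1", "segment_index": 0}
    )
    return FeatureMatrix(X, [f"f{i}" for i in range(4)], meta)


class TestRunCV:
    def test_perfect_separation_gives_100(self):
        fm = _toy_matrix(sep=8.0)
        plan = participant_folds(fm.meta, 4, seed=0)
        report = run_cv(fm, plan, "qsvm", select_k=None, with_curves=False)
        assert report.metrics["accuracy"] == 100.0

    def test_label_shuffle_near_chance(self):
        fm = _toy_matrix(sep=0.0, n=240, n_participants=24, seed=3)
        plan = participant_folds(fm.meta, 4, seed=0)
        report = run_cv(fm, plan, "qsvm", select_k=None, with_curves=False)
        assert 30.0 <= report.metrics["accuracy"] <= 70.0

    def test_every_segment_tested_once(self):
        fm = _toy_matrix()
        plan = participant_folds(fm.meta, 4, seed=0)
        report = run_cv(fm, plan, "qsvm", select_k=None, with_curves=False)
        assert sum(report.confusion.values()) == 120

    def test_fold_metrics_reported(self):
        fm = _toy_matrix()
        plan = participant_folds(fm.meta, 4, seed=0)
        report = run_cv(fm, plan, "qsvm", select_k=None)
        assert len(report.per_fold) == 4
        assert report.roc is not None and report.roc["roc_auc"] > 0.9


class TestMetrics:
    def test_printed_f1_worked_examples(self):
        # inputs are rounded to 2 decimals, so the recomputed F1 can differ
        # from an independently rounded F1 by up to one unit in the last
        # place (2PR/(P+R) from 99.88/99.83 is 99.85499...)
        assert f1_from_precision_recall(99.88, 99.83) == pytest.approx(99.86, abs=0.01)
        assert round(f1_from_precision_recall(98.43, 98.65), 2) == 98.54
        assert round(f1_from_precision_recall(98.52, 80.44), 2) == 88.57

    def test_perfect_predictions_all_100(self):
        panel = classification_metrics(tp=50, fp=0, tn=50, fn=0)
        assert all(v == 100.0 for v in panel.values())

    def test_zero_denominator_nan(self):
        panel = classification_metrics(tp=0, fp=0, tn=10, fn=0)
        assert np.isnan(panel["precision"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(tp=-1, fp=0, tn=0, fn=0)

    @settings(deadline=None, max_examples=100)
    @given(
        st.integers(1, 10_000),
        st.integers(1, 10_000),
        st.integers(1, 10_000),
        st.integers(1, 10_000),
    )
    def test_metric_identities(self, tp, fp, tn, fn):
        panel = classification_metrics(tp, fp, tn, fn)
        p, r = panel["precision"], panel["sensitivity"]
        assert panel["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)
        assert panel["accuracy"] == pytest.approx(
            100 * (tp + tn) / (tp + fp + tn + fn), abs=1e-12
        )
        assert 0 <= panel["specificity"] <= 100


class TestROCPR:
    def test_perfect_scores_auc_one(self):
        labels = np.array([1, 1, 2, 2])
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        out = roc_pr_curves(scores, labels)
        assert out["roc_auc"] == pytest.approx(1.0)
        assert out["pr_auc"] == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = np.where(rng.random(2000) < 0.5, 1, 2)
        scores = rng.standard_normal(2000)
        out = roc_pr_curves(scores, labels)
        assert out["roc_auc"] == pytest.approx(0.5, abs=0.05)

    def test_sign_reversal_maps_auc(self):
        rng = np.random.default_rng(1)
        labels = np.where(rng.random(200) < 0.5, 1, 2)
        scores = rng.standard_normal(200) + (labels == 1)
        a = roc_pr_curves(scores, labels)["roc_auc"]
        b = roc_pr_curves(-scores, labels)["roc_auc"]
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_pr_curves(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_sklearn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random(100) < 0.5, 1, 2)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 1, 2
        scores = rng.standard_normal(100) + 0.7 * (labels == 1)
        out = roc_pr_curves(scores, labels)
        assert out["roc_auc"] == pytest.approx(
            roc_auc_score(labels == 1, scores), abs=1e-10
        )
        assert out["pr_auc"] == pytest.approx(
            average_precision_score(labels == 1, scores), abs=1e-10
        )

    def test_positive_scores_orientation(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 2))
        y = np.where(X[:, 0] > 0, 1, 2)
        model = train_quadratic_svm(X, y)
        s = positive_scores(model, X)
        # scores must increase with asthma (label 1) confidence
        assert roc_auc_score(y == 1, s) > 0.9
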