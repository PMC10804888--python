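"""Fold planning, metric suite identities and the CV/grid harnesses."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from migraph import compute_metrics, hyperparameter_grid, make_folds, run_cv
from migraph.estimators import PLVCNNClassifier
from migraph.evaluation import ADJ_FILTER_GRID, ADJ_KERNEL_GRID, PLV_GRID, METRIC_COLUMNS


def brute_force_macro_f1(y_true, y_pred, labels):
    """Independent oracle: macro F1 from raw confusion counts."""
    f1s = []
    for c in labels:
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return float(np.mean(f1s))


class _LeakedLabelClassifier(BaseEstimator, ClassifierMixin):
    """Oracle predictor: looks each row up in a ground-truth table."""

    def __init__(self, table=None):
        self.table = table

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.array([self.table[row.tobytes()] for row in np.asarray(X)])

    def predict_proba(self, X):
        pred = self.predict(X)
        out = np.full((len(pred), len(self.classes_)), 1e-9)
        for i, p in enumerate(pred):
            out[i, np.searchsorted(self.classes_, p)] = 1.0
        return out / out.sum(axis=1, keepdims=True)


class TestFoldPlan:
    def test_benchmark_geometry_gives_288_per_fold(self):
        labels = np.tile(np.arange(4), 648)  # 2592 trials
        plan = make_folds(labels, k=9, runs=1, seed=0)
        sizes = np.bincount(plan.assignments[0])
        assert np.all(sizes == 288)

    def test_folds_partition_all_trials(self):
        labels = np.tile(np.arange(4), 50)
        plan = make_folds(labels, k=9, runs=3, seed=1)
        for r in range(3):
            seen = np.concatenate([plan.fold_indices(r, f)[1] for f in range(9)])
            assert sorted(seen) == list(range(200))

    def test_stratified_within_one_trial(self):
        labels = np.tile(np.arange(4), 45)
        plan = make_folds(labels, k=9, runs=2, seed=2)
        for r in range(2):
            for f in range(9):
                _, test_idx = plan.fold_indices(r, f)
                counts = np.bincount(labels[test_idx], minlength=4)
                assert counts.max() - counts.min() <= 1

    def test_determinism_and_run_variation(self):
        labels = np.tile(np.arange(4), 30)
        a = make_folds(labels, k=5, runs=2, seed=7)
        b = make_folds(labels, k=5, runs=2, seed=7)
        assert np.array_equal(a.assignments, b.assignments)
        assert not np.array_equal(a.assignments[0], a.assignments[1])

    def test_frozen_folds_reuse_one_partition(self):
        labels = np.tile(np.arange(4), 30)
        plan = make_folds(labels, k=5, runs=3, seed=4, vary_folds=False)
        assert np.array_equal(plan.assignments[0], plan.assignments[1])
        assert np.array_equal(plan.assignments[0], plan.assignments[2])

    def test_accepts_trial_container_like_objects(self):
        class Box:
            labels = np.tile(np.arange(4), 10)

        plan = make_folds(Box(), k=4, runs=1, seed=0)
        assert plan.n_trials == 40

    def test_k_larger_than_trial_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(np.arange(4), k=9)


class TestMetrics:
    def test_perfect_prediction_identity(self):
        y = np.tile(np.arange(4), 10)
        scores = np.eye(4)[y]
        rec = compute_metrics(y, y, scores)
        for key in METRIC_COLUMNS:
            assert rec[key] == pytest.approx(1.0)

    def test_micro_f1_equals_micro_precision_equals_accuracy(self, rng):
        y_true = rng.integers(0, 4, 500)
        y_pred = rng.integers(0, 4, 500)
        rec = compute_metrics(y_true, y_pred)
        assert rec["f1_micro"] == pytest.approx(rec["accuracy"], abs=1e-12)
        assert rec["precision_micro"] == pytest.approx(rec["accuracy"], abs=1e-12)

    def test_macro_f1_matches_brute_force_oracle(self, rng):
        labels = np.arange(4)
        y_true = rng.integers(0, 4, 300)
        y_pred = rng.integers(0, 4, 300)
        rec = compute_metrics(y_true, y_pred, labels=labels)
        assert rec["f1_macro"] == pytest.approx(brute_force_macro_f1(y_true, y_pred, labels))

    def test_uniform_random_scores_have_chance_auc(self, rng):
        n = 10000
        y = rng.integers(0, 4, n)
        scores = rng.dirichlet(np.ones(4), size=n)
        rec = compute_metrics(y, scores.argmax(1), scores, labels=np.arange(4))
        assert rec["roc_auc_macro"] == pytest.approx(0.5, abs=0.02)
        assert rec["roc_auc_micro"] == pytest.approx(0.5, abs=0.02)

    def test_single_class_fold_flags_auc_undefined(self):
        y = np.zeros(10, dtype=int)
        scores = np.full((10, 2), 0.5)
        with pytest.warns(UserWarning, match="single class"):
            rec = compute_metrics(y, y, scores, labels=np.arange(2))
        assert np.isnan(rec["roc_auc_macro"])


class TestRunCV:
    def test_oracle_predictor_scores_perfectly(self, rng):
        X = rng.standard_normal((80, 5))
        y = np.tile(np.arange(4), 20)
        table = {row.tobytes(): label for row, label in zip(X, y)}
        plan = make_folds(y, k=4, runs=2, seed=0)
        report = run_cv(X, y, _LeakedLabelClassifier(table), plan)
        assert report.accuracy == 1.0
        assert np.all(report.records["f1_macro"] == 1.0)

    def test_label_permuted_data_is_at_chance(self, rng):
        X = rng.standard_normal((800, 10))
        y = rng.permutation(np.tile(np.arange(4), 200))
        plan = make_folds(y, k=4, runs=2, seed=3)
        report = run_cv(X, y, LogisticRegression(max_iter=500), plan)
        assert report.accuracy == pytest.approx(0.25, abs=0.05)

    def test_micro_identity_holds_in_every_row(self, rng):
        X = rng.standard_normal((60, 4))
        y = np.tile(np.arange(3), 20)
        X[y == 1] += 2.0
        plan = make_folds(y, k=3, runs=2, seed=1)
        report = run_cv(X, y, LogisticRegression(max_iter=500), plan)
        assert np.allclose(report.records["f1_micro"], report.records["accuracy"])
        assert np.allclose(report.records["precision_micro"], report.records["accuracy"])
        assert report.accuracy_sd >= 0


class TestHyperparameterGrid:
    def test_row_count_best_flag_and_failed_rows(self, rng):
        X = rng.uniform(0, 1, (40, 10, 10)).astype(np.float32)
        y = np.tile([0, 1], 20)
        X[y == 1, 2, 7] += 1.0
        plan = make_folds(y, k=2, runs=1, seed=0)
        grid = [{"filters": (4, 8), "kernel": (2, 2)},
                {"filters": (4, 8), "kernel": (3, 3)},
                {"filters": (4, 8), "kernel": (30, 30)}]  # impossible kernel
        table = hyperparameter_grid(PLVCNNClassifier(max_epochs=2, batch_size=16),
                                    grid, X, y, plan)
        assert len(table) == 3
        assert table["failed"].tolist() == [False, False, True]
        assert table["best"].sum() == 1
        assert not table.loc[table["best"], "failed"].any()

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            hyperparameter_grid(PLVCNNClassifier(), [], None, None, None)

    def test_packaged_grids_mirror_published_sweeps(self):
        assert [g["filters"] for g in ADJ_FILTER_GRID] == [32, 64, 128, 256]
        assert [g["kernel_width"] for g in ADJ_KERNEL_GRID] == [22, 45, 65, 85]
        assert len(PLV_GRID) == 8
        assert {g["kernel"] for g in PLV_GRID} == {(2, 2), (3, 3)}
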