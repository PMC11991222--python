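"""Split/CV protocol, early stopping and the two evaluation metrics."""

import numpy as np
import pytest

from habitmine.nn import Parameter
from habitmine.training import (evaluate, split_and_fold,
                                train_with_early_stopping)


class TestSplitAndFold:
    def test_stratification_arithmetic(self):
        labels = ["A"] * 100 + ["B"] * 100 + ["C"] * 100
        plan = split_and_fold(labels, seed=0)
        assert len(plan.test_idx) == 90
        labels = np.asarray(labels)
        for cls in "ABC":
            assert abs((labels[plan.test_idx] == cls).sum() - 30) <= 1
        # inner folds partition the training portion
        all_val = np.concatenate([v for _, v in plan.folds])
        assert sorted(all_val) == sorted(plan.train_idx)

    def test_determinism_under_fixed_seed(self):
        labels = (["A"] * 40 + ["B"] * 40) * 2
        p1 = split_and_fold(labels, seed=5)
        p2 = split_and_fold(labels, seed=5)
        assert np.array_equal(p1.test_idx, p2.test_idx)
        for (f1, v1), (f2, v2) in zip(p1.folds, p2.folds):
            assert np.array_equal(f1, f2) and np.array_equal(v1, v2)

    def test_undersized_class_error_names_the_class(self):
        with pytest.raises(ValueError, match="Rare"):
            split_and_fold(["A"] * 50 + ["Rare"] * 2, folds=3)


class _ScriptedModel:
    """Stub whose validation loss follows a fixed schedule, one value per
    epoch; training batches are no-ops."""

    def __init__(self, schedule):
        self.schedule = list(schedule)
        self.epoch = -1
        self.marker = Parameter(np.zeros(1))

    def parameters(self):
        return [self.marker]

    def loss_and_grad(self, X, y):
        return 0.5

    def predict_proba(self, X, batch_size=256):
        # called once per epoch by the validation pass
        self.epoch += 1
        p = np.exp(-self.schedule[self.epoch])
        probs = np.full((len(X), 2), (1 - p))
        probs[:, 0] = p
        return probs

    def get_state(self):
        return [self.marker.value.copy(), np.array([self.epoch])]

    def set_state(self, state):
        self.restored_epoch = int(state[1][0])


@pytest.fixture
def toy_data():
    X = np.ones((4, 3), dtype=np.int64)
    y = np.zeros(4, dtype=np.int64)
    return X, y


class TestEarlyStopping:
    def test_stops_after_patience_without_improvement(self, toy_data):
        X, y = toy_data
        model = _ScriptedModel([1.0, 0.8, 0.9, 0.95, 0.97])
        hist = train_with_early_stopping(model, X, y, X, y,
                                         patience=2, max_epochs=10)
        assert hist.stopped_epoch == 4
        assert hist.best_epoch == 2
        assert model.restored_epoch == 1  # checkpoint taken at epoch 2
        assert hist.val_loss == pytest.approx([1.0, 0.8, 0.9, 0.95])

    def test_monotone_improvement_runs_to_max_epochs(self, toy_data):
        X, y = toy_data
        model = _ScriptedModel([1.0, 0.9, 0.8, 0.7, 0.6])
        hist = train_with_early_stopping(model, X, y, X, y,
                                         patience=2, max_epochs=5)
        assert hist.stopped_epoch == 5
        assert hist.best_epoch == 5

    def test_best_checkpoint_is_global_minimum(self, toy_data):
        X, y = toy_data
        model = _ScriptedModel([0.9, 0.5, 0.7, 0.6, 0.65, 0.8])
        hist = train_with_early_stopping(model, X, y, X, y,
                                         patience=4, max_epochs=6)
        assert hist.best_val_loss == min(hist.val_loss)
        assert hist.best_epoch == 2

    def test_zero_patience_rejected(self, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError):
            train_with_early_stopping(_ScriptedModel([1.0]), X, y, X, y, patience=0)

    def test_nonfinite_loss_aborts(self, toy_data):
        X, y = toy_data
        model = _ScriptedModel([1.0])
        model.loss_and_grad = lambda X, y: float("nan")
        with pytest.raises(RuntimeError, match="non-finite"):
            train_with_early_stopping(model, X, y, X, y, patience=2)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        report = evaluate(y, y, ["A", "B", "C"])
        assert report.weighted_f1 == pytest.approx(100.0)
        assert report.balanced_accuracy == pytest.approx(100.0)

    def test_balanced_accuracy_from_confusion_matrix(self):
        """Confusion matrix [[9,1],[4,6]] -> recalls 0.9, 0.6 -> 75.0."""
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.array([0] * 9 + [1] + [0] * 4 + [1] * 6)
        report = evaluate(y_true, y_pred, ["A", "B"])
        assert report.balanced_accuracy == pytest.approx(75.0)
        assert report.confusion.tolist() == [[9, 1], [4, 6]]

    def test_constant_predictor_scores_chance_level(self):
        y_true = np.array([0] * 20 + [1] * 20)
        report = evaluate(y_true, np.zeros(40, dtype=int), ["A", "B"])
        assert report.balanced_accuracy == pytest.approx(50.0)

    def test_absent_class_excluded_with_support_zero(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 1])
        report = evaluate(y_true, y_pred, ["A", "B", "C"])
        assert report.support[2] == 0
        assert report.balanced_accuracy == pytest.approx(100.0)

    def test_agreement_with_independent_reimplementation(self):
        """Cross-check against a from-scratch confusion-matrix computation
        on random prediction/label pairs."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(20, 200))
            y_true = rng.integers(0, k, size=n)
            y_pred = rng.integers(0, k, size=n)
            report = evaluate(y_true, y_pred, [f"C{i}" for i in range(k)])

            cm = np.zeros((k, k), dtype=int)
            for t, p in zip(y_true, y_pred):
                cm[t, p] += 1
            support = cm.sum(axis=1)
            recalls, f1s = [], np.zeros(k)
            for c in range(k):
                tp = cm[c, c]
                prec = tp / cm[:, c].sum() if cm[:, c].sum() else 0.0
                rec = tp / support[c] if support[c] else 0.0
                if support[c]:
                    recalls.append(rec)
                f1s[c] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            expected_wf1 = (support / support.sum() * f1s).sum() * 100
            expected_ba = np.mean(recalls) * 100
            assert report.weighted_f1 == pytest.approx(expected_wf1, abs=1e-9)
            assert report.balanced_accuracy == pytest.approx(expected_ba, abs=1e-9)
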