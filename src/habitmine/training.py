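"""Training protocol and evaluation metrics.

The protocol mirrors a standard activity-recognition setup: a stratified
70/30 train/test split, stratified 3-fold cross-validation inside the
training portion, mini-batch Adam with early stopping on validation loss,
and two scores reported as percentages — weighted F1 (per-class F1
averaged with class-support weights) and balanced accuracy (mean per-class
recall).
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split

from .models import WindowClassifier
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Index sets of the outer split and the inner CV folds."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (fit_idx, val_idx), absolute indices
    seed: int


def split_and_fold(
    labels: Sequence[str],
    *,
    train_frac: float = 0.70,
    folds: int = 3,
    seed: int = 0,
) -> SplitPlan:
    """Stratified outer split + stratified K-fold CV inside the train part.

    Deterministic under a fixed seed. Raises ValueError, naming the class,
    if any class has fewer members than ``folds`` (stratification would be
    impossible).
    """
    labels = list(labels)
    counts = Counter(labels)
    for cls, c in sorted(counts.items()):
        if c < folds:
            raise ValueError(f"class {cls!r} has only {c} examples; need >= {folds} for {folds}-fold CV")
    idx = np.arange(len(labels))
    y = np.asarray(labels)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed, shuffle=True
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_list = [
        (train_idx[fit], train_idx[val]) for fit, val in skf.split(train_idx, y[train_idx])
    ]
    return SplitPlan(train_idx, test_idx, fold_list, seed)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based
    stopped_epoch: int = 0

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch - 1]


def _validation_loss(model: WindowClassifier, X: np.ndarray, y: np.ndarray,
                     batch_size: int = 256) -> float:
    """Mean negative log-likelihood of the window-level prediction."""
    total, n = 0.0, 0
    for lo in range(0, len(X), batch_size):
        p = model.predict_proba(X[lo:lo + batch_size])
        yy = y[lo:lo + batch_size]
        total += -np.log(np.clip(p[np.arange(len(yy)), yy], 1e-12, None)).sum()
        n += len(yy)
    return total / max(n, 1)


def train_with_early_stopping(
    model: WindowClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 50,
    patience: int = 5,
    seed: int = 0,
    callback: Optional[Callable[[int, float, float], None]] = None,
) -> TrainingHistory:
    """Mini-batch Adam with early stopping on validation loss.

    Training halts once the validation loss has not improved for
    ``patience`` consecutive epochs (or at ``max_epochs``); the parameters
    of the epoch with minimum validation loss are restored into ``model``.
    Raises ValueError for ``patience < 1`` and RuntimeError on a non-finite
    loss.
    """
    if patience < 1:
        raise ValueError(f"patience must be >= 1, got {patience}")
    if len(X_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.get_state()
    bad_epochs = 0

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(X_train))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), batch_size):
            sel = order[lo:lo + batch_size]
            opt.zero_grad()
            loss = model.loss_and_grad(X_train[sel], y_train[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches} "
                    f"(lr={lr}, batch_size={batch_size})"
                )
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val = _validation_loss(model, X_val, y_val)
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_loss.append(val)
        if callback is not None:
            callback(epoch, history.train_loss[-1], val)
        if val < best_val:
            best_val = val
            best_state = model.get_state()
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
        history.stopped_epoch = epoch
        if bad_epochs >= patience:
            break
    model.set_state(best_state)
    return history


@dataclass
class EvalReport:
    """Per-class and aggregate classification scores (percent scale)."""

    class_names: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    weighted_f1: float          # 0..100
    balanced_accuracy: float    # 0..100
    confusion: np.ndarray
    n: int
    fold: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "weighted_f1": self.weighted_f1,
            "balanced_accuracy": self.balanced_accuracy,
            "confusion": self.confusion.tolist(),
            "n": self.n,
            "fold": self.fold,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [f"{'class':<16}{'prec':>8}{'recall':>8}{'f1':>8}{'support':>9}"]
        for i, name in enumerate(self.class_names):
            lines.append(
                f"{name:<16}{self.precision[i]:>8.3f}{self.recall[i]:>8.3f}"
                f"{self.f1[i]:>8.3f}{int(self.support[i]):>9d}"
            )
        lines.append(f"weighted F1        : {self.weighted_f1:.2f}")
        lines.append(f"balanced accuracy  : {self.balanced_accuracy:.2f}")
        return "\n".join(lines)


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_names: Sequence[str],
    *,
    fold: Optional[int] = None,
    seed: Optional[int] = None,
) -> EvalReport:
    """Score predictions: weighted F1 and balanced accuracy, x100.

    Classes absent from the test set are excluded from the balanced-
    accuracy mean with a warning (their recall is undefined).
    """
    if len(y_true) == 0:
        raise ValueError("empty test set")
    k = len(class_names)
    labels = np.arange(k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division for absent classes
        prec, rec, f1, supp = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0
        )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    present = supp > 0
    if not present.all():
        absent = [class_names[i] for i in np.nonzero(~present)[0]]
        logger.warning("classes absent from test set excluded from balanced accuracy: %s",
                       ", ".join(absent))
    weighted_f1 = float((supp[present] / supp.sum() * f1[present]).sum() * 100)
    balanced_accuracy = float(rec[present].mean() * 100)
    return EvalReport(
        class_names=list(class_names),
        precision=prec, recall=rec, f1=f1, support=supp,
        weighted_f1=weighted_f1, balanced_accuracy=balanced_accuracy,
        confusion=cm, n=len(y_true), fold=fold, seed=seed,
    )


def evaluate_model(model: WindowClassifier, X: np.ndarray, y: np.ndarray,
                   class_names: Sequence[str], **kwargs) -> EvalReport:
    return evaluate(y, model.predict(X), class_names, **kwargs)


def run_protocol(
    model_factory: Callable[[int], WindowClassifier],
    X: np.ndarray,
    y: np.ndarray,
    class_names: Sequence[str],
    *,
    seed: int = 0,
    folds: int = 3,
    train_frac: float = 0.70,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 30,
    patience: int = 5,
) -> tuple[list[EvalReport], list[TrainingHistory]]:
    """Full protocol: stratified split, K-fold training, test evaluation.

    One model per fold is trained on that fold's fit portion with the fold's
    validation portion driving early stopping; each trained model is scored
    on the held-out 30%. Returns the per-fold test reports (average them for
    the headline numbers) and training histories.
    """
    labels_str = [class_names[i] for i in y]
    plan = split_and_fold(labels_str, train_frac=train_frac, folds=folds, seed=seed)
    reports, histories = [], []
    for fold_id, (fit_idx, val_idx) in enumerate(plan.folds):
        model = model_factory(fold_id)
        hist = train_with_early_stopping(
            model, X[fit_idx], y[fit_idx], X[val_idx], y[val_idx],
            lr=lr, batch_size=batch_size, max_epochs=max_epochs,
            patience=patience, seed=seed + fold_id,
        )
        report = evaluate_model(model, X[plan.test_idx], y[plan.test_idx],
                                class_names, fold=fold_id, seed=seed)
        reports.append(report)
        histories.append(hist)
    return reports, histories
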