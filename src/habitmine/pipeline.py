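"""End-to-end pipeline stages and their on-disk artifacts.

Each stage is a plain function over (inputs, config, seed) writing its
artifacts into a run directory, so any stage can be re-run from the
persisted outputs of the previous one. The CLI in :mod:`habitmine.cli` is
a thin wrapper around these functions.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .casas import OTHER_LABEL, Record, label_events, read_events, write_events
from .config import PipelineConfig
from .mining import (HabitSet, MinedHabit, MiningConfig, RuleEvaluation,
                     build_transactions, evaluate_rules, mine_habits,
                     windows_to_behaviors)
from .models import WindowClassifier, build_model
from .preprocess import Vocabulary, WindowSet, segment_windows, tokenize_event
from .simulate import GroundTruth, default_scenario, generate
from .training import (EvalReport, evaluate, split_and_fold,
                       train_with_early_stopping)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def stratified_subsample(labels: Sequence[str], cap: int, seed: int) -> np.ndarray:
    """Deterministic stratified subsample of at most ``cap`` indices,
    preserving class proportions (each class keeps at least one member).
    Returns sorted indices; with cap <= 0 or cap >= N returns everything."""
    n = len(labels)
    if cap <= 0 or cap >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    picked: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        k = max(1, int(round(len(idx) / n * cap)))
        picked.append(rng.choice(idx, size=min(k, len(idx)), replace=False))
    return np.sort(np.concatenate(picked))


@dataclass
class PreparedData:
    """Windows encoded and split, ready for training.

    ``windows`` holds every window of the stream in time order (this is
    what classification and rule mining consume); ``X``/``y`` are the
    (possibly subsampled) training view that the split and CV plan index
    into.
    """

    windows: WindowSet            # full stream, time-ordered
    X: np.ndarray                 # (N, W) indices — training view
    y: np.ndarray                 # (N,) class indices — training view
    class_names: list[str]
    vocabulary: Vocabulary
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]


def prepare_windows(records: list[Record], cfg: PipelineConfig) -> PreparedData:
    """Label, subsample, split, build the vocabulary and encode windows.

    The training view is a stratified subsample capped at
    ``cfg.max_windows``; the vocabulary is built only from events covered
    by its training windows, so no test-only token receives an index
    (test-time unknowns map to UNK).
    """
    labelled = label_events(records)
    if not labelled:
        raise StageError("preprocess", "no events to window")
    n = len(labelled)
    ends = list(range(n - 1, -1, -cfg.step))[::-1]
    window_labels = [labelled[e][1] for e in ends]

    keep = stratified_subsample(window_labels, cfg.max_windows, cfg.seed)
    sub_ends = [ends[i] for i in keep]
    sub_labels = [window_labels[i] for i in keep]
    if not cfg.include_other:
        sel = [i for i, lab in enumerate(sub_labels) if lab != OTHER_LABEL]
        sub_ends = [sub_ends[i] for i in sel]
        sub_labels = [sub_labels[i] for i in sel]

    plan = split_and_fold(sub_labels, train_frac=cfg.train_frac,
                          folds=cfg.folds, seed=cfg.seed)

    # events covered by at least one training window
    covered = np.zeros(n, dtype=bool)
    for wi in plan.train_idx:
        e = sub_ends[wi]
        covered[max(0, e - cfg.window_size + 1):e + 1] = True
    train_tokens = [
        tokenize_event(labelled[i][0], numeric_bin_width=cfg.numeric_bin_width)
        for i in np.nonzero(covered)[0]
    ]
    vocab = Vocabulary.from_tokens(train_tokens)

    windows = segment_windows(labelled, vocab, cfg.window_size, step=cfg.step,
                              label_mode=cfg.label_mode,
                              numeric_bin_width=cfg.numeric_bin_width)
    # map training-view window end positions back to rows of the full set
    pos_of_end = {e: i for i, e in enumerate(range(n - 1, -1, -cfg.step))}
    rows = [len(windows) - 1 - pos_of_end[e] for e in sub_ends]
    X = windows.X[rows]

    class_names = sorted(set(windows.labels) if cfg.include_other
                         else set(sub_labels))
    class_index = {c: i for i, c in enumerate(class_names)}
    y = np.array([class_index[windows.labels[r]] for r in rows], dtype=np.int64)
    return PreparedData(windows, X, y, class_names, vocab,
                        plan.train_idx, plan.test_idx, plan.folds)


@dataclass
class TrainedModel:
    model: WindowClassifier
    report: EvalReport
    history_val_loss: list[float]


def train_classifier(data: PreparedData, cfg: PipelineConfig,
                     *, seed: Optional[int] = None) -> TrainedModel:
    """Train the configured model on fold 0 of the CV plan and score it on
    the held-out test windows."""
    seed = cfg.seed if seed is None else seed
    model = build_model(cfg.model, len(data.class_names), cfg.window_size,
                        data.vocabulary.n_indices, embedding=cfg.embedding,
                        depth_scale=cfg.depth_scale, seed=seed)
    fit_idx, val_idx = data.folds[0]
    history = train_with_early_stopping(
        model, data.X[fit_idx], data.y[fit_idx], data.X[val_idx], data.y[val_idx],
        lr=cfg.lr, batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
        patience=cfg.patience, seed=seed,
    )
    report = evaluate(data.y[data.test_idx], model.predict(data.X[data.test_idx]),
                      data.class_names, seed=seed)
    return TrainedModel(model, report, history.val_loss)


def classify_stream(model: WindowClassifier, windows: WindowSet,
                    class_names: Sequence[str], batch_size: int = 512) -> list[str]:
    """Predicted label for every window, in time order."""
    pred = model.predict(windows.X, batch_size=batch_size)
    return [class_names[i] for i in pred]


@dataclass
class MiningResult:
    transactions: list
    all_rules: list[MinedHabit]
    habits: HabitSet
    eval_before: Optional[RuleEvaluation] = None
    eval_after: Optional[RuleEvaluation] = None

    def summary(self) -> dict:
        out = {
            "n_transactions": len(self.transactions),
            "rules_before_filter": len(self.all_rules),
            "rules_after_filter": len(self.habits.kept),
        }
        if self.eval_before is not None and self.eval_after is not None:
            out.update({
                "tp_before": self.eval_before.tp,
                "tp_after": self.eval_after.tp,
                "precision_before": self.eval_before.precision,
                "precision_after": self.eval_after.precision,
            })
        return out


def mine_stream(window_labels: Sequence[str], end_timestamps, mining_cfg: MiningConfig,
                truth: Optional[GroundTruth] = None) -> MiningResult:
    """Behavior collapse -> transactions -> FP-Growth -> rules -> temporal
    filter, optionally scored against the planted ground truth."""
    behaviors = windows_to_behaviors(list(window_labels), list(end_timestamps),
                                     min_run=mining_cfg.min_run)
    transactions = build_transactions(behaviors, mining_cfg)
    if not transactions:
        raise StageError("mine", "no transactions (no recognised behaviors)")
    all_rules, habits = mine_habits(transactions, mining_cfg)
    result = MiningResult(transactions, all_rules, habits)
    if truth is not None:
        result.eval_before = evaluate_rules(all_rules, truth.planted_habits)
        result.eval_after = evaluate_rules(habits.kept, truth.planted_habits)
    return result


def support_confidence_grid(
    transactions, truth: Optional[GroundTruth], mining_cfg: MiningConfig,
    supports: Sequence[float], confidences: Sequence[float],
):
    """Sweep a support x confidence grid (the 20x20 sensitivity experiment
    runs 0.75..0.85 on both axes) and tabulate rule counts and precision."""
    import pandas as pd
    from dataclasses import replace

    rows = []
    for s in supports:
        for c in confidences:
            cfg = replace(mining_cfg, min_support=s, min_confidence=c)
            all_rules, habits = mine_habits(transactions, cfg)
            row = {"min_support": s, "min_confidence": c,
                   "rules_before_filter": len(all_rules),
                   "rules_after_filter": len(habits.kept)}
            if truth is not None:
                ev = evaluate_rules(habits.kept, truth.planted_habits)
                row["tp"] = ev.tp
                row["precision"] = ev.precision
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpointing and the full run


def save_checkpoint(model: WindowClassifier, path, meta: dict) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[WindowClassifier, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    model = build_model(meta["model"], meta["n_classes"], meta["window_size"],
                        meta["n_indices"], embedding=meta["embedding"],
                        depth_scale=meta["depth_scale"], seed=meta["seed"])
    model.set_state(state)
    return model, meta


def run(cfg: PipelineConfig, outdir: str | Path,
        *, log_path: Optional[str | Path] = None) -> dict:
    """Execute simulate -> preprocess -> train -> classify -> mine ->
    evaluate, persisting artifacts and provenance into ``outdir``.

    With ``log_path`` set, that CASAS log is used instead of simulating
    (ground-truth-based rule precision is then unavailable unless a
    ``ground_truth.json`` sits beside the log). Returns a summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": cfg.seed,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    truth: Optional[GroundTruth] = None
    if log_path is None:
        spec = default_scenario(seed=cfg.seed, n_days=cfg.n_days)
        records, truth = generate(spec)
        write_events(records, outdir / "events.log",
                     header=f"synthetic home log, seed={spec.seed}")
        truth.to_json(outdir / "ground_truth.json")
    else:
        records = list(read_events(log_path))
        sidecar = Path(log_path).with_name("ground_truth.json")
        if sidecar.exists():
            truth = GroundTruth.from_json(sidecar)

    data = prepare_windows(records, cfg)
    data.vocabulary.save(outdir / "vocab.tsv")

    summary: dict = {"n_windows": len(data.windows), "classes": data.class_names}

    if cfg.use_true_labels:
        window_labels = list(data.windows.labels)
    else:
        trained = train_classifier(data, cfg)
        trained.report.to_json(outdir / "metrics.json")
        (outdir / "metrics.txt").write_text(trained.report.summary() + "\n")
        save_checkpoint(trained.model, outdir / "checkpoint.npz", {
            "model": cfg.model, "embedding": cfg.embedding,
            "depth_scale": cfg.depth_scale, "window_size": cfg.window_size,
            "n_classes": len(data.class_names), "n_indices": data.vocabulary.n_indices,
            "seed": cfg.seed,
        })
        summary["weighted_f1"] = trained.report.weighted_f1
        summary["balanced_accuracy"] = trained.report.balanced_accuracy
        window_labels = classify_stream(trained.model, data.windows, data.class_names)

    result = mine_stream(window_labels, data.windows.end_timestamps, cfg.mining, truth)
    result.habits.to_tsv(outdir / "habits.tsv")
    result.habits.to_json(outdir / "habits.json")
    with (outdir / "transactions.basket").open("w", encoding="utf-8") as fh:
        for t in result.transactions:
            fh.write(",".join(f"{a}@{b}" for a, b in sorted(t.items)) + "\n")
    summary.update(result.summary())
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
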