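"""Confusion-matrix metrics, per-class and macro F1, tenfold CV harness.

Binary metrics (AF positive):

    ACC  = (TN + TP) / (TN + TP + FN + FP)
    Sens = TP / (TP + FN)       Spec = TN / (TN + FP)

Challenge-style scoring: per-class F1_c = 2 TP / (2 TP + FP + FN) from
one-vs-rest confusions, and the overall F1 is the mean over the normal,
AF and other-rhythm classes only — noise records are still scored (their
misclassification erodes the three per-class F1s) but the noise class's
own F1 never enters the average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "binary_metrics",
    "f1_per_class",
    "macro_f1",
    "multiclass_confusions",
    "evaluate_predictions",
    "tenfold_cv",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    f1_per_class: dict[str, float] = field(default_factory=dict)
    macro_f1: float | None = None
    loss: float | None = None
    confusion: ConfusionCounts | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1_n": self.f1_per_class.get("N"),
            "f1_a": self.f1_per_class.get("A"),
            "f1_o": self.f1_per_class.get("O"),
            "macro_f1": self.macro_f1,
            "loss": self.loss,
            "confusion": (
                {"tp": self.confusion.tp, "fp": self.confusion.fp,
                 "tn": self.confusion.tn, "fn": self.confusion.fn}
                if self.confusion else None
            ),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def confusion(y_true: Sequence, y_pred: Sequence, positive_class=1) -> ConfusionCounts:
    """Exact TP/FP/TN/FN tallies with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
    )


def binary_metrics(c: ConfusionCounts) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity); a ratio with empty denominator is None."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    acc = (c.tn + c.tp) / c.total
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return acc, sens, spec


def f1_per_class(c: ConfusionCounts) -> float:
    """F1_c = 2TP / (2TP + FP + FN); 0 when the denominator is 0."""
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom > 0 else 0.0


def macro_f1(f1n: float, f1a: float, f1o: float) -> float:
    """Mean of the normal / AF / other per-class F1s; noise never averaged."""
    for name, v in (("f1n", f1n), ("f1a", f1a), ("f1o", f1o)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return (f1n + f1a + f1o) / 3.0


def multiclass_confusions(y_true: Sequence[str], y_pred: Sequence[str],
                          classes=("N", "A", "O", "~")) -> dict[str, ConfusionCounts]:
    """One-vs-rest confusion per class from a single multi-class prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    unknown = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not unknown <= set(classes):
        raise ValueError(f"unknown labels {sorted(unknown - set(classes))}")
    return {cls: confusion(y_true, y_pred, positive_class=cls) for cls in classes}


def evaluate_predictions(y_true, y_pred, loss: float | None = None) -> MetricsReport:
    """Binary MetricsReport from 0/1 labels and predictions (AF = 1)."""
    c = confusion(y_true, y_pred, positive_class=1)
    acc, sens, spec = binary_metrics(c)
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         loss=loss, confusion=c)


def write_confusion_csv(c: ConfusionCounts, path: str | Path) -> Path:
    """Confusion matrix as CSV; rows = actual class, columns = predicted."""
    path = Path(path)
    path.write_text(
        ",pred_non_af,pred_af\n"
        f"actual_non_af,{c.tn},{c.fp}\n"
        f"actual_af,{c.fn},{c.tp}\n"
    )
    return path


def format_confusion(c: ConfusionCounts) -> str:
    """Console rendering; rows = actual, columns = predicted."""
    return (
        "              pred non-AF   pred AF\n"
        f"actual non-AF   {c.tn:9d} {c.fp:9d}\n"
        f"actual AF       {c.fn:9d} {c.tp:9d}"
    )


def _fold_assignment(n: int, k: int, seed: int) -> list[np.ndarray]:
    idx = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(idx, k)]


def tenfold_cv(segments, model_factory, train_config, seed: int = 0, k: int = 10):
    """K-fold cross-validation: train on k-1 folds, score the held-out fold.

    ``model_factory(fold_index)`` builds a fresh model per fold.  Returns
    (per-fold MetricsReport list, pooled MetricsReport) where the pooled
    confusion is the element-wise sum of the fold confusions.
    """
    from .training import cross_entropy, train  # local import: avoids a cycle

    n = len(segments)
    if n < k:
        raise ValueError(f"need at least {k} records for {k}-fold CV, got {n}")
    labels = np.array([s.label.binary_label for s in segments])
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for cross-validation")
    folds = _fold_assignment(n, k, seed)
    reports: list[MetricsReport] = []
    pooled = ConfusionCounts()
    for f, test_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate([folds[j] for j in range(k) if j != f]))
        model = model_factory(f)
        # inside a fold: no further test cut; 3:1 train/val split of the k-1 folds
        inner = train_config
        fold_split_seed = train_config.seed + 1000 * (f + 1)
        rng = np.random.default_rng(fold_split_seed)
        perm = rng.permutation(train_idx)
        n_val = max(1, int(0.25 * len(perm)))
        from .training import SplitIndices

        split = SplitIndices(perm[n_val:], perm[:n_val], test_idx)
        model, _, _ = train(model, segments, inner, split=split)
        x = np.stack([segments[i].values for i in test_idx]).astype(np.float32)
        y = labels[test_idx]
        model.eval()
        probs = model.predict_proba(x)
        report = evaluate_predictions(y, (probs >= 0.5).astype(int),
                                      loss=cross_entropy(y, probs))
        reports.append(report)
        pooled = pooled + report.confusion
    acc, sens, spec = binary_metrics(pooled)
    pooled_report = MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                                  confusion=pooled)
    return reports, pooled_report
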