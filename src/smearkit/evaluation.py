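"""Pixel-, object- and classification-level evaluation metrics.

Definitions (TP/TN/FP/FN are confusion counts over the evaluated units,
pixels or samples):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

    IoU  = |A ∩ B| / |A ∪ B|        Dice = 2|A ∩ B| / (|A| + |B|)

with the identity Dice = 2*IoU / (1 + IoU).  Multiclass confusion
matrices use rows = actual class, columns = predicted class.  ROC/AUC is
computed one-vs-rest per class by trapezoidal integration, pooled for the
micro average and unweighted-averaged over classes for the macro
average.  Fold aggregation reports the unweighted mean (and population
std) over per-fold rows, formatted to two decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "BinaryMetrics",
    "confusion_matrix",
    "binary_metrics",
    "overlap_metrics",
    "roc_auc",
    "aggregate_folds",
    "multiclass_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class BinaryMetrics:
    """Metric values; a ``None`` entry means the denominator was zero and
    the metric is undefined (flagged in ``undefined``)."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: tuple = ()


def confusion_matrix(true_labels, predicted_labels, n_classes: int = 9) -> np.ndarray:
    """Multiclass confusion matrix, rows = actual, columns = predicted."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors are misaligned")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    return _sk_confusion(t, p, labels=np.arange(n_classes))


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Accuracy / precision / recall / F1 from binary confusion counts;
    zero-denominator metrics come back as None with a flag, never as 0."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = ratio(c.tp + c.tn, c.total, "accuracy")
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    rec = ratio(c.tp, c.tp + c.fn, "recall")
    if prec is None or rec is None or prec + rec == 0:
        if "precision" not in undefined and "recall" not in undefined:
            undefined.append("f1")
        f1 = None
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return BinaryMetrics(acc, prec, rec, f1, tuple(undefined))


def overlap_metrics(pred_mask: np.ndarray, true_mask: np.ndarray) -> tuple[float, float]:
    """(IoU, Dice) of two binary masks; two empty masks count as (1, 1)."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    size_sum = int(a.sum()) + int(b.sum())
    if union == 0:
        return 1.0, 1.0
    return inter / union, 2.0 * inter / size_sum


def roc_auc(true_labels, probability_matrix) -> dict:
    """One-vs-rest ROC AUC per class plus micro and macro averages.

    ``probability_matrix`` is (n_samples, n_classes).  A class absent from
    the true labels has undefined AUC and is excluded from the macro mean
    with a warning.
    """
    y = np.asarray(true_labels)
    p = np.asarray(probability_matrix, dtype=float)
    if p.ndim != 2 or len(y) != len(p):
        raise ValueError("probability matrix must be (n_samples, n_classes)")
    n_classes = p.shape[1]
    per_class: dict[int, float | None] = {}
    defined = []
    for k in range(n_classes):
        pos = y == k
        if pos.all() or not pos.any():
            warnings.warn(f"class {k} absent from one side of true labels; AUC undefined")
            per_class[k] = None
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), p[:, k])
        auc = float(np.trapezoid(tpr, fpr))
        per_class[k] = auc
        defined.append(auc)
    onehot = np.zeros_like(p)
    onehot[np.arange(len(y)), y] = 1.0
    fpr, tpr, _ = roc_curve(onehot.ravel(), p.ravel())
    micro = float(np.trapezoid(tpr, fpr))
    macro = float(np.mean(defined)) if defined else float("nan")
    return {"per_class": per_class, "micro": micro, "macro": macro}


def aggregate_folds(reports: list[dict], decimals: int = 2) -> pd.DataFrame:
    """Aggregate per-fold metric dicts into a table with Mean ± Std rows.

    Input: one dict per fold mapping metric name -> value (same keys in
    every fold).  Output: DataFrame with one row per fold plus ``mean``
    and ``std`` rows (population std), all rounded to ``decimals``.
    """
    if not reports:
        raise ValueError("at least one fold report is required")
    df = pd.DataFrame(reports, index=[f"fold_{i + 1}" for i in range(len(reports))])
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=0)
    out = pd.concat([df, mean.to_frame("mean").T, std.to_frame("std").T])
    return out.round(decimals)


def write_report(out_dir, true_labels, predicted_labels, probability_matrix=None,
                 class_names=None) -> dict:
    """Write a classification report to ``out_dir``: metrics JSON,
    confusion matrix as CSV and rendered heatmap, and per-class ROC
    points as CSV when probabilities are given.  Returns the metrics."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_classes = (len(class_names) if class_names
                 else int(max(np.max(true_labels), np.max(predicted_labels))) + 1)
    names = list(class_names) if class_names else [str(i) for i in range(n_classes)]
    rep = multiclass_report(true_labels, predicted_labels, n_classes)
    cm = rep.pop("confusion")
    pd.DataFrame(cm, index=names, columns=names).to_csv(out / "confusion_matrix.csv")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(n_classes), names, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(n_classes), names, fontsize=7)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("actual class")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(out / "confusion_matrix.png", dpi=120)
    plt.close(fig)

    if probability_matrix is not None:
        auc = roc_auc(true_labels, probability_matrix)
        rep["auc_micro"] = auc["micro"]
        rep["auc_macro"] = auc["macro"]
        rows = []
        y = np.asarray(true_labels)
        p = np.asarray(probability_matrix, dtype=float)
        for k in range(n_classes):
            pos = y == k
            if pos.all() or not pos.any():
                continue
            fpr, tpr, thr = roc_curve(pos.astype(int), p[:, k])
            for f, t, s in zip(fpr, tpr, thr):
                rows.append({"class": names[k], "fpr": f, "tpr": t, "threshold": s})
        pd.DataFrame(rows).to_csv(out / "roc_points.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(rep, indent=2))
    return rep


def multiclass_report(true_labels, predicted_labels, n_classes: int = 9) -> dict:
    """Aggregate accuracy plus macro-averaged one-vs-rest precision,
    recall and F1 (the averaging scheme behind single headline numbers)."""
    cm = confusion_matrix(true_labels, predicted_labels, n_classes)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else math.nan
    precs, recs, f1s = [], [], []
    for k in range(n_classes):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        tn = total - tp - fp - fn
        m = binary_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
        if m.precision is not None:
            precs.append(m.precision)
        if m.recall is not None:
            recs.append(m.recall)
        if m.f1 is not None:
            f1s.append(m.f1)
    return {
        "accuracy": accuracy,
        "precision": float(np.mean(precs)) if precs else math.nan,
        "recall": float(np.mean(recs)) if recs else math.nan,
        "f1": float(np.mean(f1s)) if f1s else math.nan,
        "confusion": cm,
    }
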