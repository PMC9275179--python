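"""Classifier evaluation: confusion matrices, MCC, ROC AUC, reports.

Metrics follow the standard definitions: accuracy ``(TP+TN)/total``,
recall ``TP/(TP+FN)``, precision ``TP/(TP+FP)``, and the Matthews
correlation coefficient, binary form
``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` with the
zero-denominator -> 0 convention.  For K classes the generalized
(multi-category R_K) coefficient is used; it reduces to the binary form
at K = 2.  ROC curves are one-vs-rest with trapezoidal AUC; micro
averaging pools the (sample, class) indicator stream, macro averaging is
the unweighted mean of per-class AUCs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "BinaryMetrics",
    "RocResult",
    "ClassificationReport",
    "basic_metrics",
    "mcc",
    "roc_auc",
    "normalized_heatmap",
    "classification_report",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: Sequence[str], y_pred: Sequence[str],
                         classes: Sequence[str] | None = None) -> "ConfusionMatrix":
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(classes, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_counts(self, positive_class: str) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating ``positive_class`` one-vs-rest."""
        i = self.classes.index(positive_class)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


@dataclass
class BinaryMetrics:
    accuracy: float
    precision: float
    recall: float
    precision_defined: bool = True

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)


def basic_metrics(cm: ConfusionMatrix, positive_class: str) -> BinaryMetrics:
    """One-vs-rest accuracy, precision and recall for one class.

    Precision with no positive predictions is reported as 0 with
    ``precision_defined=False``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.binary_counts(positive_class)
    accuracy = (tp + tn) / cm.total
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp + fp == 0:
        return BinaryMetrics(accuracy, 0.0, recall, precision_defined=False)
    return BinaryMetrics(accuracy, tp / (tp + fp), recall)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient, generalized to K classes.

    Uses the multi-category form
    ``(c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))``
    where ``c`` is the trace, ``s`` the total, ``t_k`` the true and
    ``p_k`` the predicted counts per class; equals the familiar binary
    formula at K = 2.  A zero denominator yields 0 by convention.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    C = cm.counts.astype(float)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)  # true counts
    p = C.sum(axis=0)  # predicted counts
    num = c * s - float(t @ p)
    den = math.sqrt(max(s * s - float(p @ p), 0.0) *
                    max(s * s - float(t @ t), 0.0))
    if den == 0.0:
        return 0.0
    return float(num / den)


@dataclass
class RocResult:
    curves: dict[str, pd.DataFrame]  # class -> (threshold, fpr, tpr)
    per_class_auc: dict[str, float]
    micro_auc: float
    macro_auc: float
    skipped_classes: list[str] = field(default_factory=list)


def _binary_roc(y: np.ndarray, scores: np.ndarray) -> tuple[pd.DataFrame, float]:
    """One ROC curve by score thresholding; AUC by trapezoidal rule.

    Thresholds are the distinct score values (descending); points are
    deduplicated.  ``y`` is a boolean positive indicator.
    """
    order = np.argsort(-scores, kind="stable")
    y = y[order].astype(float)
    s = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), y.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1.0 - y)[distinct]
    n_pos, n_neg = y.sum(), y.size - y.sum()
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve.drop_duplicates(subset=["fpr", "tpr"]), auc


def roc_auc(y_true: Sequence[str], scores: np.ndarray,
            classes: Sequence[str]) -> RocResult:
    """One-vs-rest ROC curves plus micro- and macro-averaged AUC.

    ``scores`` is (n_samples, n_classes) aligned with ``classes``.  A
    class without both positives and negatives is skipped (flagged);
    truth confined to a single class overall is an error.
    """
    y_true = np.asarray(list(y_true))
    scores = np.asarray(scores, dtype=float)
    classes = list(classes)
    if scores.shape != (y_true.size, len(classes)):
        raise ValueError("scores must be (n_samples, n_classes)")
    if len(set(y_true)) < 2:
        raise ValueError("ROC needs at least two distinct true classes")
    curves: dict[str, pd.DataFrame] = {}
    aucs: dict[str, float] = {}
    skipped: list[str] = []
    pooled_y, pooled_s = [], []
    for j, cls in enumerate(classes):
        y = y_true == cls
        pooled_y.append(y)
        pooled_s.append(scores[:, j])
        if y.all() or not y.any():
            skipped.append(cls)
            continue
        curves[cls], aucs[cls] = _binary_roc(y, scores[:, j])
    if not aucs:
        raise ValueError("no class had both positive and negative samples")
    macro = float(np.mean(list(aucs.values())))
    _, micro = _binary_roc(np.concatenate(pooled_y), np.concatenate(pooled_s))
    return RocResult(curves, aucs, micro_auc=micro, macro_auc=macro,
                     skipped_classes=skipped)


def normalized_heatmap(cm: ConfusionMatrix) -> np.ndarray:
    """Row-normalized confusion proportions (each true-class row sums to 1;
    all-zero rows stay zero)."""
    counts = cm.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(totals > 0, counts / totals, 0.0)
    return out


@dataclass
class ClassificationReport:
    """Full evaluation bundle for one model on one test split."""

    confusion: ConfusionMatrix
    per_class: pd.DataFrame  # accuracy, precision, recall, f1 per class
    mcc: float
    heatmap: np.ndarray
    roc: RocResult | None = None
    overall_accuracy: float = 0.0

    def to_dict(self) -> dict:
        out = {
            "classes": list(self.confusion.classes),
            "confusion": self.confusion.counts.tolist(),
            "per_class": {c: {k: float(v) for k, v in row.items()}
                          for c, row in self.per_class.iterrows()},
            "overall_accuracy": self.overall_accuracy,
            "mcc": self.mcc,
            "heatmap": [[round(v, 10) for v in row] for row in self.heatmap],
        }
        if self.roc is not None:
            out["roc"] = {"micro_auc": self.roc.micro_auc,
                          "macro_auc": self.roc.macro_auc,
                          "per_class_auc": self.roc.per_class_auc,
                          "skipped_classes": self.roc.skipped_classes}
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    def write_roc_tsv(self, path: str | Path) -> None:
        if self.roc is None:
            raise ValueError("report has no ROC result")
        frames = []
        for cls, curve in self.roc.curves.items():
            frame = curve.copy()
            frame.insert(0, "class", cls)
            frames.append(frame)
        pd.concat(frames).to_csv(path, sep="\t", index=False)


def classification_report(y_true: Sequence[str], y_pred: Sequence[str],
                          scores: np.ndarray | None = None,
                          classes: Sequence[str] | None = None,
                          ) -> ClassificationReport:
    """Assemble the full evaluation bundle from predictions (and optional
    per-class scores, which enable the ROC block)."""
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, classes)
    rows = {}
    for cls in cm.classes:
        m = basic_metrics(cm, cls)
        rows[cls] = {"accuracy": m.accuracy, "precision": m.precision,
                     "recall": m.recall, "f1": m.f1}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    roc = None
    if scores is not None:
        roc = roc_auc(y_true, scores, cm.classes)
    overall = float(np.trace(cm.counts)) / cm.total
    return ClassificationReport(cm, per_class, mcc(cm), normalized_heatmap(cm),
                                roc=roc, overall_accuracy=overall)
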