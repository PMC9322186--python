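"""Accuracy assessment of classification maps.

Cluster indices from an unsupervised run carry no class meaning, so the first
step aligns clusters to ground-truth classes by optimal one-to-one assignment
on the contingency table (surplus clusters fall back to their majority
class).  The confusion matrix then follows the remote-sensing convention:
columns hold the true pixel counts per class, rows the predicted counts.
From it come overall accuracy (trace over total), Cohen's kappa with the
chance agreement generalised to C classes, and one-vs-rest precision, recall
and F1 per class plus their macro average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import EvaluationError, UndefinedKappaError

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "map_clusters",
    "overall_accuracy",
    "kappa",
    "precision_recall_f1",
    "EvalReport",
    "evaluate_labels",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows = predicted class, columns = true class."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise EvaluationError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise EvaluationError("confusion matrix counts must be >= 0")
        if not self.class_names:
            self.class_names = [str(i) for i in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def binary_counts(self, c: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) for class index ``c``."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[c, :].sum() - tp)  # predicted c, truly other
        fn = int(self.counts[:, c].sum() - tp)  # truly c, predicted other
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn


def confusion_matrix(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    class_names: Optional[Sequence[str]] = None,
    n_classes: Optional[int] = None,
) -> ConfusionMatrix:
    """Build a rows=predicted, columns=true count matrix over class indices."""
    t = np.asarray(y_true, dtype=int).ravel()
    p = np.asarray(y_pred, dtype=int).ravel()
    if t.size != p.size:
        raise EvaluationError("label vectors differ in length")
    if t.size == 0:
        raise EvaluationError("no labelled pixels to evaluate")
    C = int(n_classes) if n_classes else int(max(t.max(), p.max())) + 1
    counts = np.zeros((C, C), dtype=np.int64)
    np.add.at(counts, (p, t), 1)
    names = list(class_names) if class_names else [str(i) for i in range(C)]
    return ConfusionMatrix(counts=counts, class_names=names)


def map_clusters(pred_labels, true_labels) -> dict[int, int]:
    """Align cluster indices to class indices.

    The one-to-one part is the assignment on the cluster x class contingency
    table that maximises the matched pixel count (Hungarian algorithm);
    clusters beyond the class count map to their majority class.
    """
    p = np.asarray(pred_labels, dtype=int).ravel()
    t = np.asarray(true_labels, dtype=int).ravel()
    keep = (p >= 0) & (t >= 0)
    p, t = p[keep], t[keep]
    if p.size == 0:
        raise EvaluationError("no overlapping labelled pixels")
    clusters = np.unique(p)
    classes = np.unique(t)
    cont = np.zeros((clusters.size, classes.size), dtype=np.int64)
    np.add.at(cont, (np.searchsorted(clusters, p), np.searchsorted(classes, t)), 1)
    rows, cols = linear_sum_assignment(cont, maximize=True)
    mapping = {int(clusters[r]): int(classes[c]) for r, c in zip(rows, cols)}
    for k, cl in enumerate(clusters):  # surplus clusters -> majority class
        if int(cl) not in mapping:
            mapping[int(cl)] = int(classes[cont[k].argmax()])
    return mapping


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correctly classified pixels over all pixels (trace over total)."""
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (po - pe) / (1 - pe).

    ``po`` is the overall accuracy; the chance agreement ``pe`` is the sum
    over classes of (row sum x column sum) / total^2, which reduces to the
    familiar binary TP/TN/FP/FN form at C = 2.
    """
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    total = cm.total
    po = overall_accuracy(cm)
    pe = float(
        np.sum(cm.counts.sum(axis=1) * cm.counts.sum(axis=0)) / (total * total)
    )
    if pe >= 1.0:
        raise UndefinedKappaError("chance agreement is 1; kappa undefined")
    return float((po - pe) / (1.0 - pe))


def precision_recall_f1(cm: ConfusionMatrix, c: int) -> tuple[float, float, float]:
    """One-vs-rest precision, recall and F1 for class index ``c``.

    A zero denominator leaves the affected quantity as NaN and forces
    F1 = 0 by convention.
    """
    if not 0 <= c < cm.n_classes:
        raise EvaluationError(f"class index {c} outside matrix of {cm.n_classes}")
    tp, _, fp, fn = cm.binary_counts(c)
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f1)


@dataclass
class EvalReport:
    """Full accuracy report for one classification run."""

    matrix: ConfusionMatrix
    overall_accuracy: float
    kappa: Optional[float]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    macro_f1: float
    mapping: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _num(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v
        return {
            "class_names": self.matrix.class_names,
            "confusion_matrix": self.matrix.counts.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "kappa": _num(self.kappa),
            "precision": [_num(v) for v in self.precision],
            "recall": [_num(v) for v in self.recall],
            "f1": self.f1,
            "macro_f1": self.macro_f1,
            "mapping": {str(k): v for k, v in self.mapping.items()},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = ["class\tprecision\trecall\tf1"]
        for name, p, r, f in zip(self.matrix.class_names, self.precision,
                                 self.recall, self.f1):
            lines.append(f"{name}\t{p:.4f}\t{r:.4f}\t{f:.4f}")
        lines.append(f"overall_accuracy\t{self.overall_accuracy:.4f}")
        if self.kappa is not None:
            lines.append(f"kappa\t{self.kappa:.4f}")
        lines.append(f"macro_f1\t{self.macro_f1:.4f}")
        return "\n".join(lines)


def evaluate_labels(
    true_labels,
    pred_labels,
    class_names: Optional[Sequence[str]] = None,
    align: bool = True,
) -> EvalReport:
    """Score a predicted label map (or vector) against ground truth.

    Negative labels on either side mark masked/unlabelled pixels and are
    excluded.  When ``align`` is True the predicted cluster indices are first
    mapped onto classes with :func:`map_clusters`.
    """
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(pred_labels, dtype=int).ravel()
    if t.size != p.size:
        raise EvaluationError("prediction and truth must cover the same pixels")
    keep = (t >= 0) & (p >= 0)
    t, p = t[keep], p[keep]
    if t.size == 0:
        raise EvaluationError("no overlapping labelled pixels")
    mapping: dict[int, int] = {}
    if align:
        mapping = map_clusters(p, t)
        p = np.array([mapping[int(v)] for v in p])
    C = int(max(t.max(), p.max())) + 1
    cm = confusion_matrix(t, p, class_names=class_names, n_classes=C)
    prf = [precision_recall_f1(cm, c) for c in range(C)]
    precision = [v[0] for v in prf]
    recall = [v[1] for v in prf]
    f1 = [v[2] for v in prf]
    try:
        kap: Optional[float] = kappa(cm)
    except UndefinedKappaError:
        kap = None
    return EvalReport(
        matrix=cm,
        overall_accuracy=overall_accuracy(cm),
        kappa=kap,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(np.mean(f1)),
        mapping=mapping,
    )
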