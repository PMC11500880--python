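"""Multiclass evaluation: confusion matrix, derived rates, one-vs-rest ROC-AUC.

Per-class quantities come from the one-vs-rest decomposition of the
confusion matrix (rows = true class, columns = predicted class):

    accuracy    = trace / total
    precision_c = TP / (TP + FP)        recall_c = TP / (TP + FN)
    F1_c        = 2 P R / (P + R)       specificity_c = TN / (TN + FP)

Precision, recall and F1 aggregate support-weighted, which makes the
aggregate recall coincide exactly with accuracy; specificity aggregates
macro (unweighted), since a support-weighted true-negative rate would be
dominated by the majority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .core import IGPAWarning, LabelVector, PredictionMatrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "classification_report",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Count table: counts[t, p] = samples of true class t predicted as p."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        names = tuple(str(c) for c in self.class_names)
        if len(names) != counts.shape[0]:
            raise ValueError("class_names misaligned with counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_marginals(self) -> dict[str, np.ndarray]:
        """One-vs-rest TP/FP/FN/TN per class."""
        tp = np.diag(self.counts).astype(float)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate and per-class metrics, all as fractions in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    per_class: dict[str, dict[str, float]]
    support: dict[str, int]
    averaging: dict[str, str]
    roc_auc_per_class: dict[str, float] | None = None
    roc_auc_macro: float | None = None

    def as_percentages(self, decimals: int = 2) -> dict[str, float]:
        """Headline numbers on the 0-100 scale, rounded half-even."""
        out = {
            name: float(np.round(100 * getattr(self, name), decimals))
            for name in ("accuracy", "precision", "recall", "f1", "specificity")
        }
        if self.roc_auc_macro is not None:
            out["roc_auc_macro"] = float(np.round(100 * self.roc_auc_macro, decimals))
        return out

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "per_class": self.per_class,
            "support": self.support,
            "averaging": self.averaging,
        }
        if self.roc_auc_per_class is not None:
            d["roc_auc_per_class"] = self.roc_auc_per_class
            d["roc_auc_macro"] = self.roc_auc_macro
        return d


def confusion_matrix(
    pred_labels: LabelVector | np.ndarray,
    truth: LabelVector | np.ndarray,
    n_classes: int,
    class_names: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Tally predictions against truth over a fixed class set."""
    pred = pred_labels.labels if isinstance(pred_labels, LabelVector) else np.asarray(pred_labels)
    true = truth.labels if isinstance(truth, LabelVector) else np.asarray(truth)
    if pred.size == 0 or true.size == 0:
        raise ValueError("empty inputs")
    if pred.size != true.size:
        raise ValueError(f"length mismatch: {pred.size} predictions, {true.size} labels")
    if np.any(pred >= n_classes) or np.any(true >= n_classes) or np.any(pred < 0) or np.any(true < 0):
        raise ValueError(f"labels out of range for {n_classes} classes")
    counts = _sk_confusion(true, pred, labels=np.arange(n_classes))
    names = class_names or tuple(str(i) for i in range(n_classes))
    return ConfusionMatrix(counts, names)


def classification_report(cm: ConfusionMatrix) -> MetricsReport:
    """Derive all rates from a confusion matrix.

    Per-class values with a zero denominator are reported as 0 with a
    warning rather than dropped.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    m = cm.ovr_marginals()
    tp, fp, fn, tn = m["tp"], m["fp"], m["fn"], m["tn"]
    support = tp + fn

    def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        zero = den == 0
        if np.any(zero):
            warnings.warn(
                f"{what} undefined for class(es) "
                f"{[cm.class_names[i] for i in np.where(zero)[0]]}; reported as 0",
                IGPAWarning,
                stacklevel=3,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
        return out

    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    pr_sum = precision + recall
    f1 = _safe_div(2 * precision * recall, pr_sum, "f1")
    specificity = _safe_div(tn, tn + fp, "specificity")

    w = support / support.sum()
    per_class = {
        name: {
            "precision": float(precision[i]),
            "recall": float(recall[i]),
            "f1": float(f1[i]),
            "specificity": float(specificity[i]),
        }
        for i, name in enumerate(cm.class_names)
    }
    return MetricsReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        precision=float(np.dot(w, precision)),
        recall=float(np.dot(w, recall)),
        f1=float(np.dot(w, f1)),
        specificity=float(specificity.mean()),
        per_class=per_class,
        support={name: int(support[i]) for i, name in enumerate(cm.class_names)},
        averaging={
            "precision": "weighted",
            "recall": "weighted",
            "f1": "weighted",
            "specificity": "macro",
        },
    )


def roc_auc(
    preds: PredictionMatrix, truth: LabelVector
) -> tuple[dict[str, float], float]:
    """One-vs-rest ROC-AUC per class plus the macro average.

    A class absent from the truth (or covering all of it) has no defined
    AUC; such classes are reported as NaN and excluded from the macro
    average.  If no class has both positives and negatives, raises.
    """
    true = truth.labels if isinstance(truth, LabelVector) else np.asarray(truth)
    if preds.n_samples != true.size:
        raise ValueError("prediction rows and labels misaligned")
    per_class: dict[str, float] = {}
    defined: list[float] = []
    for i, name in enumerate(preds.class_names):
        pos = true == i
        if pos.all() or not pos.any():
            per_class[name] = float("nan")
            continue
        auc = float(roc_auc_score(pos.astype(int), preds.probs[:, i]))
        per_class[name] = auc
        defined.append(auc)
    if not defined:
        raise ValueError("AUC undefined for every class (single-class truth)")
    return per_class, float(np.mean(defined))
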