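"""Confusion matrices and macro-averaged classification metrics.

Conventions: confusion rows are actual classes, columns predicted,
ordered LR, LS, PSw, Sw.  Macro metrics are unweighted means over
classes; classes with no predictions (zero column sum) have undefined
precision and are excluded from the macro precision/F1 means with a
warning.  All percentages are on the 0-100 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

CLASS_NAMES = ["LR", "LS", "PSw", "Sw"]


def confusion_matrix(y_true, y_pred, n_classes: int = 4) -> np.ndarray:
    """Count matrix: ``counts[a, p] = #{i : y_true[i]=a, y_pred[i]=p}``."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if len(y) and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return counts


def row_normalize(counts: np.ndarray) -> np.ndarray:
    """Row percentages; empty rows become NaN (undefined)."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, counts / sums * 100.0, np.nan)


def macro_recall_from_row_pct(row_pct: np.ndarray) -> float:
    """Macro recall from a row-normalized matrix: the mean of its diagonal
    (support-independent, so computable from percentages alone)."""
    diag = np.diagonal(np.asarray(row_pct, dtype=float))
    return float(np.nanmean(diag))


def macro_metrics(counts: np.ndarray) -> dict:
    """ACC and macro precision/recall/F1 (all in %) from a count matrix."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diagonal(counts)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, diag / row_sums, np.nan)
        precision = np.where(col_sums > 0, diag / col_sums, np.nan)
        f1 = 2 * precision * recall / (precision + recall)
        f1 = np.where((precision + recall) > 0, f1, 0.0)
    if np.any(col_sums == 0):
        missing = [CLASS_NAMES[i] for i in np.flatnonzero(col_sums == 0)]
        warnings.warn(
            f"no predictions for class(es) {missing}; precision undefined, "
            "excluded from macro means"
        )
    return {
        "acc": float(diag.sum() / total * 100.0),
        "macro_pr": float(np.nanmean(precision) * 100.0),
        "macro_rc": float(np.nanmean(recall) * 100.0),
        "macro_f1": float(np.nanmean(f1) * 100.0),
        "per_class": {
            CLASS_NAMES[i]: {
                "precision": float(precision[i] * 100.0),
                "recall": float(recall[i] * 100.0),
                "f1": float(f1[i] * 100.0),
            }
            for i in range(counts.shape[0])
        },
    }


@dataclass
class EvalReport:
    """Evaluation summary: confusion matrix (counts and row %), overall
    accuracy and macro precision/recall/F1, all percentages 0-100."""

    confusion_counts: np.ndarray
    confusion_row_pct: np.ndarray
    acc: float
    macro_pr: float
    macro_rc: float
    macro_f1: float
    per_class: dict

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int = 4) -> "EvalReport":
        counts = confusion_matrix(y_true, y_pred, n_classes)
        m = macro_metrics(counts)
        return cls(
            confusion_counts=counts,
            confusion_row_pct=row_normalize(counts),
            acc=m["acc"],
            macro_pr=m["macro_pr"],
            macro_rc=m["macro_rc"],
            macro_f1=m["macro_f1"],
            per_class=m["per_class"],
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion_counts"] = self.confusion_counts.tolist()
        d["confusion_row_pct"] = np.round(self.confusion_row_pct, 4).tolist()
        d["class_names"] = CLASS_NAMES
        return d
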