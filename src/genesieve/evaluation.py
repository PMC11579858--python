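"""Multiclass evaluation: confusion matrix, macro metrics, one-vs-rest ROC/AUC.

Accuracy, recall, precision and F1 are defined per class one-vs-rest from the
confusion matrix (TP, TN, FP, FN) and macro-averaged with equal class weight;
micro averages are emitted alongside for transparency.  Macro-F1 is the mean
of per-class F1 values, not the harmonic mean of macro-precision and
macro-recall.  ROC curves come from a threshold sweep on each class's
predicted probability; AUC is the trapezoidal area, which with the tie
convention equals the probability that a random positive outranks a random
negative (ties counting one half).  An empty-class 0/0 in any ratio is
reported as 0 with a warning so reports never carry NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "EvaluationReport", "evaluate", "roc_points",
           "auc_trapezoid"]


@dataclass
class ConfusionMatrix:
    """K × K count table; rows are true classes, columns predicted."""

    class_names: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be K × K")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_counts(self, i: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) for class index ``i``."""
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 reported as 0", stacklevel=3)
        return 0.0
    return num / den


@dataclass
class EvaluationReport:
    """All headline metrics for one prediction run."""

    accuracy: float
    precision: float        # macro
    recall: float           # macro
    f1: float               # macro
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_class: pd.DataFrame
    confusion: ConfusionMatrix
    roc: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)
    macro_auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision,
            "recall_macro": self.recall,
            "f1_macro": self.f1,
            "precision_micro": self.micro_precision,
            "recall_micro": self.micro_recall,
            "f1_micro": self.micro_f1,
            "auc_macro": self.macro_auc,
            "auc_per_class": dict(self.auc),
            "per_class": {
                c: {k: float(v) for k, v in row.items()}
                for c, row in self.per_class.to_dict(orient="index").items()
            },
            "confusion": {
                "class_names": self.confusion.class_names,
                "counts": self.confusion.counts.tolist(),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def summary(self) -> str:
        lines = [
            f"accuracy        {self.accuracy:.4f}",
            f"macro precision {self.precision:.4f}",
            f"macro recall    {self.recall:.4f}",
            f"macro F1        {self.f1:.4f}",
        ]
        if np.isfinite(self.macro_auc):
            lines.append(f"macro AUC       {self.macro_auc:.4f}")
        return "\n".join(lines)


def roc_points(y_true_binary: np.ndarray, scores: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve as (FPR, TPR) arrays from (0,0) to (1,1).

    Computed by sweeping a threshold over the distinct score values; both
    coordinate sequences are monotone non-decreasing.
    """
    y = np.asarray(y_true_binary, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep only the last point of each tied-score block
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under an ROC polyline by the trapezoidal rule."""
    return float(np.trapezoid(tpr, fpr))


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             y_proba: np.ndarray | None = None,
             class_names: list[str] | None = None) -> EvaluationReport:
    """Score multiclass predictions.

    Parameters
    ----------
    y_true, y_pred
        Equal-length label arrays; every predicted label must belong to the
        class set.
    y_proba
        Optional cells × classes probability rows (columns ordered as
        ``class_names``); enables ROC/AUC.
    class_names
        Evaluation class order; defaults to sorted unique true labels.
        Mandatory when ``y_proba`` is given, to pin the column order.

    Returns
    -------
    EvaluationReport
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    if class_names is None:
        if y_proba is not None:
            raise ValueError("class_names is required when y_proba is given")
        class_names = sorted(set(y_true))
    class_names = [str(c) for c in class_names]
    known = set(class_names)
    bad = sorted({str(v) for v in np.r_[y_true, y_pred]} - known)
    if bad:
        raise ValueError(f"labels outside the class set: {bad[:5]}")

    k = len(class_names)
    idx = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[str(t)], idx[str(p)]] += 1
    cm = ConfusionMatrix(class_names, counts)

    rows = []
    for i, c in enumerate(class_names):
        tp, tn, fp, fn = cm.binary_counts(i)
        if tp + fn == 0:
            warnings.warn(f"class {c!r} absent from y_true; its recall is "
                          "reported as 0", stacklevel=2)
        rec = _safe_div(tp, tp + fn, f"recall[{c}]")
        pre = _safe_div(tp, tp + fp, f"precision[{c}]")
        f1 = _safe_div(2 * pre * rec, pre + rec, f"F1[{c}]")
        rows.append({"class": c, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
                     "precision": pre, "recall": rec, "f1": f1,
                     "support": tp + fn})
    per_class = pd.DataFrame(rows).set_index("class")

    total = cm.total
    accuracy = _safe_div(int(np.trace(counts)), total, "accuracy")
    tp_sum = int(per_class["tp"].sum())
    fp_sum = int(per_class["fp"].sum())
    fn_sum = int(per_class["fn"].sum())
    micro_p = _safe_div(tp_sum, tp_sum + fp_sum, "micro precision")
    micro_r = _safe_div(tp_sum, tp_sum + fn_sum, "micro recall")
    micro_f1 = _safe_div(2 * micro_p * micro_r, micro_p + micro_r, "micro F1")

    report = EvaluationReport(
        accuracy=accuracy,
        precision=float(per_class["precision"].mean()),
        recall=float(per_class["recall"].mean()),
        f1=float(per_class["f1"].mean()),
        micro_precision=micro_p, micro_recall=micro_r, micro_f1=micro_f1,
        per_class=per_class, confusion=cm,
    )

    if y_proba is not None:
        y_proba = np.asarray(y_proba, dtype=float)
        if y_proba.shape != (len(y_true), k):
            raise ValueError("y_proba must be n_cells × n_classes")
        aucs = {}
        for i, c in enumerate(class_names):
            mask = np.asarray([str(t) == c for t in y_true])
            if mask.all() or not mask.any():
                continue  # one-vs-rest ROC undefined for this class
            fpr, tpr = roc_points(mask, y_proba[:, i])
            report.roc[c] = (fpr, tpr)
            aucs[c] = auc_trapezoid(fpr, tpr)
        report.auc = aucs
        if aucs:
            report.macro_auc = float(np.mean(list(aucs.values())))
    return report
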