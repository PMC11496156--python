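"""Evaluation metrics and cross-validation splits.

Accuracy, precision, sensitivity (recall) and F1 are the standard report
for profusion grading; precision/sensitivity/F1 are macro-averaged over the
four levels so the rare level 3 counts as much as the abundant level 0.
Cells with a zero denominator (a class never predicted, or absent from the
evaluation set) are defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

__all__ = ["MetricsReport", "FoldSplit", "confusion_matrix", "compute_metrics",
           "crossval_split", "DataValidationError", "EmptyEvaluationError"]


class DataValidationError(ValueError):
    pass


class EmptyEvaluationError(ValueError):
    pass


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_f1: float
    per_class_precision: np.ndarray
    per_class_sensitivity: np.ndarray
    per_class_f1: np.ndarray
    confusion: np.ndarray       # rows = true level, columns = predicted level

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_f1": self.macro_f1,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_sensitivity": self.per_class_sensitivity.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "confusion": self.confusion.tolist(),
        }


def confusion_matrix(true_levels, predicted_levels, n_classes: int) -> np.ndarray:
    """C x C matrix; entry (t, p) counts samples with true t predicted p."""
    t = np.asarray(true_levels, dtype=np.intp)
    p = np.asarray(predicted_levels, dtype=np.intp)
    if t.shape != p.shape or t.ndim != 1:
        raise DataValidationError("true and predicted label sequences must be equal-length 1-D")
    for name, arr in (("true", t), ("predicted", p)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if bad.size:
            raise DataValidationError(f"{name} labels outside [0, {n_classes - 1}] at {bad.tolist()[:20]}")
    return _sk_confusion(t, p, labels=np.arange(n_classes))


def compute_metrics(confusion: np.ndarray) -> MetricsReport:
    """Derive the metric report from a confusion matrix.

    Per-class precision = diagonal / column sum, sensitivity = diagonal /
    row sum, F1 their harmonic mean; macro values are unweighted means over
    classes; accuracy = trace / total.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise DataValidationError("confusion must be a square non-negative matrix")
    total = cm.sum()
    if total == 0:
        raise EmptyEvaluationError("confusion matrix is all zeros; nothing was evaluated")
    diag = np.diag(cm).astype(np.float64)
    col = cm.sum(axis=0).astype(np.float64)
    row = cm.sum(axis=1).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        sensitivity = np.where(row > 0, diag / row, 0.0)
        denom = precision + sensitivity
        f1 = np.where(denom > 0, 2 * precision * sensitivity / np.where(denom > 0, denom, 1.0), 0.0)
    return MetricsReport(
        accuracy=float(diag.sum() / total),
        macro_precision=float(precision.mean()),
        macro_sensitivity=float(sensitivity.mean()),
        macro_f1=float(f1.mean()),
        per_class_precision=precision,
        per_class_sensitivity=sensitivity,
        per_class_f1=f1,
        confusion=cm,
    )


@dataclass
class FoldSplit:
    """k disjoint, stratified folds of sample indices."""

    folds: list                 # list of index arrays, one per fold
    seed: int

    def iter_train_test(self):
        all_idx = np.concatenate(self.folds)
        for f in self.folds:
            mask = np.isin(all_idx, f)
            yield np.sort(all_idx[~mask]), np.sort(f)


def crossval_split(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified k-fold split, deterministic given the seed.

    Per-class counts across folds differ by at most one.  A class with
    fewer than k samples triggers a warning (sklearn's best-effort
    stratification still applies).
    """
    labels = np.asarray(labels, dtype=np.intp)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > labels.size:
        raise ValueError(f"k={k} exceeds the number of samples ({labels.size})")
    counts = np.bincount(labels)
    small = np.flatnonzero((counts > 0) & (counts < k))
    if small.size:
        warnings.warn(f"classes {small.tolist()} have fewer than {k} samples; "
                      "stratification is best-effort", stacklevel=2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        folds = [test for _, test in skf.split(np.zeros(labels.size), labels)]
    return FoldSplit(folds=folds, seed=seed)
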