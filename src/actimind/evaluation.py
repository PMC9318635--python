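"""Model evaluation: confusion matrices, one-vs-rest metrics, CV, ROC.

Per-class precision, recall and F1 come from one-vs-rest reductions of the
3x3 confusion matrix.  The single per-model Matthews correlation
coefficient is computed by summing the one-vs-rest TP/TN/FP/FN counts over
the classes and applying the binary MCC formula to the sums (micro
averaging); the Gorodkin multiclass R_k is available as an alternative.
Zero-denominator cases return 0 with a logged warning, since degenerate
folds are common in small synthetic runs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateDataError, FoldError
from .features import DayStageDataset
from .model import ForestConfig, TrainedModel, predict, predict_proba, train_forest

__all__ = [
    "ConfusionMatrix",
    "CrossValResult",
    "EvaluationReport",
    "confusion_from_labels",
    "ovr_counts",
    "per_class_prf",
    "f1_from_precision_recall",
    "binary_mcc_from_counts",
    "multiclass_mcc",
    "gorodkin_mcc",
    "accuracy",
    "kfold_cv",
    "roc_ovr",
    "evaluate_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("confusion matrix must be square over the class order")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


def confusion_from_labels(
    y_true, y_pred, classes: Sequence[int] = (0, 1, 2)
) -> ConfusionMatrix:
    counts = skmetrics.confusion_matrix(y_true, y_pred, labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def ovr_counts(cm: ConfusionMatrix, class_k: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for class ``class_k``."""
    if class_k not in cm.classes:
        raise ValueError(f"unknown class {class_k}")
    i = cm.classes.index(class_k)
    c = np.asarray(cm.counts)
    tp = int(c[i, i])
    fp = int(c[:, i].sum() - tp)
    fn = int(c[i, :].sum() - tp)
    tn = int(c.sum() - tp - fp - fn)
    return tp, tn, fp, fn


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s: zero denominator, returning 0", what)
        return 0.0
    return num / den


def per_class_prf(cm: ConfusionMatrix, class_k: int) -> tuple[float, float, float]:
    """One-vs-rest precision, recall, and their harmonic mean (F1)."""
    tp, _, fp, fn = ovr_counts(cm, class_k)
    precision = _safe_div(tp, tp + fp, f"precision[{class_k}]")
    recall = _safe_div(tp, tp + fn, f"recall[{class_k}]")
    f1 = _safe_div(2 * precision * recall, precision + recall, f"f1[{class_k}]")
    return precision, recall, f1


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return _safe_div(2 * precision * recall, precision + recall, "f1")


def binary_mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation from binary TP/TN/FP/FN counts; 0 on a zero
    denominator."""
    num = tn * tp - fn * fp
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return _safe_div(num, den, "mcc")


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Single MCC per model: the binary formula applied to the one-vs-rest
    TP/TN/FP/FN counts summed over the classes (micro averaging).

    Note the summed counts feel every class's TN mass, so this statistic
    deliberately differs from Gorodkin's R_k (see :func:`gorodkin_mcc`)
    except in degenerate cases.
    """
    if cm.total == 0:
        raise DegenerateDataError("all-zero confusion matrix")
    tp = tn = fp = fn = 0
    for k in cm.classes:
        tpk, tnk, fpk, fnk = ovr_counts(cm, k)
        tp, tn, fp, fn = tp + tpk, tn + tnk, fp + fpk, fn + fnk
    return binary_mcc_from_counts(tp, tn, fp, fn)


def gorodkin_mcc(y_true, y_pred) -> float:
    """Gorodkin's multiclass R_k (alternative MCC generalization)."""
    return float(skmetrics.matthews_corrcoef(y_true, y_pred))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace over total count."""
    if cm.total == 0:
        raise DegenerateDataError("empty confusion matrix")
    return float(np.trace(np.asarray(cm.counts)) / cm.total)


@dataclass(frozen=True)
class CrossValResult:
    fold_accuracies: tuple[float, ...]
    maximum: float
    minimum: float
    overall: float


def kfold_cv(
    dataset: DayStageDataset, config: ForestConfig, k: int = 5, seed: int = 0
) -> CrossValResult:
    """Stratified k-fold cross-validation accuracy.

    Overall accuracy pools correct predictions across all folds, so it is
    guaranteed to lie between the minimum and maximum fold accuracies.
    """
    y = np.asarray(dataset.y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise FoldError(f"every class needs >= {k} segments for {k}-fold CV")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    correct = 0
    for train_idx, test_idx in splitter.split(dataset.X, y):
        model = train_forest(dataset.subset(train_idx), config)
        pred = predict(model, dataset.subset(test_idx).X)
        hits = int((pred == y[test_idx]).sum())
        correct += hits
        fold_acc.append(hits / len(test_idx))
    return CrossValResult(
        fold_accuracies=tuple(fold_acc),
        maximum=max(fold_acc),
        minimum=min(fold_acc),
        overall=correct / dataset.n,
    )


def roc_ovr(labels, scores, class_k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC curve (FPR, TPR arrays) and trapezoid-rule area."""
    y = (np.asarray(labels) == class_k).astype(int)
    if y.min() == y.max():
        raise ValueError(f"class {class_k}: need both positive and negative examples")
    fpr, tpr, _ = skmetrics.roc_curve(y, np.asarray(scores), drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area


@dataclass(frozen=True)
class EvaluationReport:
    """Per-stage evaluation: confusion, per-class P/R/F1, MCC, ROC, CV."""

    stage: str
    confusion: ConfusionMatrix
    per_class: dict[int, dict[str, float]]
    mcc: float
    accuracy: float
    roc: dict[int, dict[str, object]]
    cv: CrossValResult | None = None

    def to_dict(self) -> dict:
        out = {
            "stage": self.stage,
            "confusion": np.asarray(self.confusion.counts).tolist(),
            "classes": list(self.confusion.classes),
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "mcc": self.mcc,
            "accuracy": self.accuracy,
            "roc": {
                str(k): {"fpr": list(v["fpr"]), "tpr": list(v["tpr"]), "area": v["area"]}
                for k, v in self.roc.items()
            },
        }
        if self.cv is not None:
            out["cv"] = {
                "fold_accuracies": list(self.cv.fold_accuracies),
                "max": self.cv.maximum,
                "min": self.cv.minimum,
                "overall": self.cv.overall,
            }
        return out

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_model(
    model: TrainedModel,
    test: DayStageDataset,
    cv: CrossValResult | None = None,
) -> EvaluationReport:
    """Score a trained model on held-out segments of one day stage."""
    y_pred = predict(model, test.X)
    proba = predict_proba(model, test.X)
    cm = confusion_from_labels(test.y, y_pred, classes=model.classes)
    per_class = {}
    roc = {}
    y = np.asarray(test.y)
    for j, k in enumerate(model.classes):
        p, r, f1 = per_class_prf(cm, k)
        per_class[k] = {"precision": p, "recall": r, "f1": f1}
        if (y == k).any() and (y != k).any():
            fpr, tpr, area = roc_ovr(y, proba[:, j], k)
            roc[k] = {"fpr": fpr, "tpr": tpr, "area": area}
    return EvaluationReport(
        stage=test.stage,
        confusion=cm,
        per_class=per_class,
        mcc=multiclass_mcc(cm),
        accuracy=accuracy(cm),
        roc=roc,
        cv=cv,
    )
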