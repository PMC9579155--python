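"""Binary-classification evaluation: confusion counts, ACC/SEN/PRE/F1, ROC/AUC.

Labels use the {-1, +1} convention with +1 = nodule.  Sensitivity is recall
on the nodule class; precision is the fraction of predicted nodules that are
real; F1 is their harmonic mean.  The ROC curve is swept over all distinct
decision values and the AUC is the trapezoidal area, which coincides with
the Mann-Whitney probability that a random positive outranks a random
negative (ties counted 1/2).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = ["ConfusionCounts", "Scores", "RocCurve", "confusion", "scores", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Scores:
    """Accuracy, sensitivity (recall), precision and F1.

    Ratios with a zero denominator are reported as ``nan`` with a warning,
    except F1, which is 0.0 (with a warning) whenever sensitivity and
    precision are both zero or either is undefined.
    """

    accuracy: float
    sensitivity: float
    precision: float
    f1: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "precision": self.precision, "f1": self.f1}


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray                 # sensitivity
    fpr: np.ndarray                 # 1 - specificity
    auc: float

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["threshold", "fpr", "tpr"])
            for t, f, s in zip(self.thresholds, self.fpr, self.tpr):
                w.writerow([t, f, s])


def _check_labels(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError(f"{name} must contain only -1/+1 labels")
    return y


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts for -1/+1 label vectors of equal length."""
    y_true = _check_labels(y_true, "y_true")
    y_pred = _check_labels(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    pos, predpos = y_true == 1, y_pred == 1
    return ConfusionCounts(
        tp=int(np.sum(pos & predpos)),
        tn=int(np.sum(~pos & ~predpos)),
        fp=int(np.sum(~pos & predpos)),
        fn=int(np.sum(pos & ~predpos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting nan", RuntimeWarning)
        return float("nan")
    return num / den


def scores(c: ConfusionCounts) -> Scores:
    """ACC, SEN, PRE and F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("no samples to score")
    acc = (c.tp + c.tn) / c.total
    sen = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    pre = _ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(sen) or np.isnan(pre) or (sen + pre) == 0:
        warnings.warn("F1 undefined; reporting 0.0 by convention", RuntimeWarning)
        f1 = 0.0
    else:
        f1 = 2.0 * sen * pre / (sen + pre)
    return Scores(accuracy=acc, sensitivity=sen, precision=pre, f1=f1)


def roc_auc(y_true, decision_values) -> RocCurve:
    """ROC curve (sensitivity vs false-positive rate) and trapezoidal AUC."""
    y_true = _check_labels(y_true, "y_true")
    dec = np.asarray(decision_values, float)
    if y_true.shape != dec.shape:
        raise ValueError("labels and decision values must have equal length")
    if np.unique(y_true).size < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, thr = _roc_curve(y_true, dec, pos_label=1)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(_trapezoid_auc(fpr, tpr)))


def report_json(s: Scores, c: ConfusionCounts, roc: RocCurve | None = None) -> str:
    """Serialize a metrics report (scores, counts, optional AUC) as JSON."""
    obj = {"scores": s.as_dict(),
           "confusion": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}}
    if roc is not None:
        obj["auc"] = roc.auc
    return json.dumps(obj, indent=2)
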