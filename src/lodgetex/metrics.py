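"""Multiclass evaluation: confusion matrix, overall accuracy, Cohen's kappa,
one-vs-rest precision/recall/F1, and per-class ROC / precision-recall curves.

Conventions: confusion-matrix rows are the actual class, columns the
predicted class, ordered NL, ML, HL, SL.  Overall accuracy OA = trace/N;
kappa = (Po - Pe)/(1 - Pe) with Po = OA and Pe the marginal chance
agreement; misclassification rate = 1 - OA.  One-vs-rest per class c:
TP = C[c,c], FP = column sum - TP, FN = row sum - TP; zero denominators
yield 0 with a flag.  ROC AUC is trapezoidal over all score thresholds
(equal scores grouped); AP is the step-wise precision-recall sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synth import CLASS_ORDER

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "overall_accuracy",
    "kappa",
    "per_class_prf",
    "roc_pr_curves",
    "evaluate",
    "evaluate_matrix",
]


@dataclass
class ConfusionMatrix:
    C: np.ndarray  # rows actual, cols predicted
    labels: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.int64)
        k = len(self.labels)
        if self.C.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix")
        if (self.C < 0).any():
            raise ValueError("negative counts")
        if self.N == 0:
            raise ValueError("empty confusion matrix")

    @property
    def N(self) -> int:
        return int(self.C.sum())


def confusion_matrix(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str] = CLASS_ORDER,
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    lut = {str(c): i for i, c in enumerate(labels)}
    unknown = (set(map(str, y_true)) | set(map(str, y_pred))) - set(lut)
    if unknown:
        raise ValueError(f"unknown label(s) {sorted(unknown)}")
    k = len(labels)
    C = np.zeros((k, k), dtype=np.int64)
    for a, p in zip(y_true, y_pred):
        C[lut[str(a)], lut[str(p)]] += 1
    return ConfusionMatrix(C, tuple(str(c) for c in labels))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    return float(np.trace(cm.C) / cm.N)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement from the matrix marginals."""
    n = cm.N
    po = np.trace(cm.C) / n
    rows = cm.C.sum(axis=1)
    cols = cm.C.sum(axis=0)
    pe = float(rows @ cols) / (n * n)
    if pe >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: chance agreement is 1")
    return float((po - pe) / (1.0 - pe))


@dataclass
class ClassPRF:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate: bool = False  # a zero denominator was reported as 0


def per_class_prf(cm: ConfusionMatrix) -> dict[str, ClassPRF]:
    out: dict[str, ClassPRF] = {}
    rows = cm.C.sum(axis=1)
    cols = cm.C.sum(axis=0)
    for i, cls in enumerate(cm.labels):
        tp = int(cm.C[i, i])
        fp = int(cols[i] - tp)
        fn = int(rows[i] - tp)
        tn = int(cm.N - tp - fp - fn)
        degenerate = False
        if tp + fp > 0:
            precision = tp / (tp + fp)
        else:
            precision, degenerate = 0.0, True
        if tp + fn > 0:
            recall = tp / (tp + fn)
        else:
            recall, degenerate = 0.0, True
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1, degenerate = 0.0, True
        out[cls] = ClassPRF(precision, recall, f1, tp, fp, fn, tn, degenerate)
    return out


def _binary_roc(y: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC for one binary problem; equal scores
    are grouped into a single threshold step."""
    order = np.argsort(-score, kind="stable")
    y = y[order]
    s = score[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct].astype(float)
    fps = (distinct + 1) - tps
    P, Nn = y.sum(), len(y) - y.sum()
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / Nn]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def _binary_pr(y: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall points and step-wise average precision."""
    order = np.argsort(-score, kind="stable")
    y = y[order]
    s = score[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct].astype(float)
    n_pred = (distinct + 1).astype(float)
    P = float(y.sum())
    precision = tps / n_pred
    recall = tps / P
    prev_r = np.r_[0.0, recall[:-1]]
    ap = float(np.sum((recall - prev_r) * precision))
    return np.r_[0.0, recall], np.r_[1.0, precision], ap


@dataclass
class ClassCurves:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    recall: np.ndarray
    precision: np.ndarray
    ap: float


def roc_pr_curves(
    y_true: Sequence[str],
    proba: np.ndarray,
    labels: Sequence[str] = CLASS_ORDER,
) -> dict[str, ClassCurves]:
    """One-vs-rest ROC and precision-recall per class, with AUC and AP."""
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape != (len(y_true), len(labels)):
        raise ValueError("probability matrix shape mismatch")
    out: dict[str, ClassCurves] = {}
    for j, cls in enumerate(labels):
        y = (y_true == cls).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"ROC/PR undefined for class {cls!r}: one-class truth")
        fpr, tpr, auc = _binary_roc(y, proba[:, j])
        recall, precision, ap = _binary_pr(y, proba[:, j])
        out[cls] = ClassCurves(fpr, tpr, auc, recall, precision, ap)
    return out


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    oa: float
    kappa: float
    misclassification_rate: float
    per_class: dict[str, ClassPRF]
    curves: dict[str, ClassCurves] | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "labels": list(self.confusion.labels),
            "confusion": self.confusion.C.tolist(),
            "n": self.confusion.N,
            "oa": self.oa,
            "kappa": self.kappa,
            "misclassification_rate": self.misclassification_rate,
            "per_class": {
                c: {
                    "precision": v.precision,
                    "recall": v.recall,
                    "f1": v.f1,
                    "tp": v.tp,
                    "fp": v.fp,
                    "fn": v.fn,
                    "tn": v.tn,
                }
                for c, v in self.per_class.items()
            },
        }
        if self.curves is not None:
            d["curves"] = {
                c: {"auc": v.auc, "ap": v.ap} for c, v in self.curves.items()
            }
        d.update(self.meta)
        return d


def evaluate_matrix(cm: ConfusionMatrix) -> EvaluationReport:
    """Full report from a bare confusion matrix (no probability curves)."""
    oa = overall_accuracy(cm)
    return EvaluationReport(
        confusion=cm,
        oa=oa,
        kappa=kappa(cm),
        misclassification_rate=1.0 - oa,
        per_class=per_class_prf(cm),
    )


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    proba: np.ndarray | None = None,
    labels: Sequence[str] = CLASS_ORDER,
) -> EvaluationReport:
    """Full report from predictions (and optionally probabilities)."""
    cm = confusion_matrix(y_true, y_pred, labels)
    report = evaluate_matrix(cm)
    if proba is not None:
        report.curves = roc_pr_curves(y_true, proba, labels)
    return report


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding used in reports (0.005 -> 0.01, not banker's)."""
    factor = 10**decimals
    return float(np.floor(x * factor + 0.5) / factor)
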