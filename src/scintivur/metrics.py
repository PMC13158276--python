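"""Evaluation metrics for binary VUR classification.

Confusion matrices may carry fractional entries: when the ten fold-specific
models are each evaluated on the same held-out test cohort, the element-wise
mean of their count matrices is a real-valued matrix, and all derived metrics
(accuracy, sensitivity, specificity, precision, F1, Cohen's kappa) are
computed on those reals. Rounding happens only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "FoldAggregate",
    "aggregate_bilateral",
    "compute_metrics",
    "roc_auc",
    "aggregate_folds",
    "clinician_report",
    "CLINICIAN_SINGLE_KIDNEY",
    "CLINICIAN_BILATERAL",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion matrix; entries are non-negative reals.

    Layout follows the usual convention: rows are ground truth, columns are
    predictions, positive = VUR present on at least one side.
    """

    tn: float
    fp: float
    fn: float
    tp: float

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            if getattr(self, name) < 0:
                raise ValueError(f"confusion-matrix entry {name} must be >= 0")
        if self.total <= 0:
            raise ValueError("confusion matrix must have positive total")

    @property
    def total(self) -> float:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=bool)
        yp = np.asarray(y_pred, dtype=bool)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tn=float(np.sum(~yt & ~yp)),
            fp=float(np.sum(~yt & yp)),
            fn=float(np.sum(yt & ~yp)),
            tp=float(np.sum(yt & yp)),
        )

    @classmethod
    def average(cls, matrices: Iterable["ConfusionMatrix"]) -> "ConfusionMatrix":
        """Element-wise mean of count matrices (fold averaging)."""
        ms = list(matrices)
        if not ms:
            raise ValueError("need at least one matrix")
        return cls(
            tn=float(np.mean([m.tn for m in ms])),
            fp=float(np.mean([m.fp for m in ms])),
            fn=float(np.mean([m.fn for m in ms])),
            tp=float(np.mean([m.tp for m in ms])),
        )


#: Clinician reading confusion matrices (single-kidney and bilateral tasks)
#: used as worked-example inputs for the agreement metrics.
CLINICIAN_SINGLE_KIDNEY = ConfusionMatrix(tn=278, fp=200, fn=54, tp=136)
CLINICIAN_BILATERAL = ConfusionMatrix(tn=129, fp=41, fn=61, tp=115)


@dataclass(frozen=True)
class MetricSet:
    """Derived classification metrics; undefined ratios are NaN, never 0."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    kappa: float
    positive_rate_true: float
    positive_rate_predicted: float
    auc: float = float("nan")

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.__dict__.items()}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision, F1 and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e computed
    from the row/column marginals of the confusion matrix; it is the
    chance-corrected agreement between prediction and reference standard.
    """
    n = cm.total
    p_o = (cm.tn + cm.tp) / n
    # marginal fractions: actual +/- and predicted +/-
    act_pos = (cm.tp + cm.fn) / n
    act_neg = (cm.tn + cm.fp) / n
    pred_pos = (cm.tp + cm.fp) / n
    pred_neg = (cm.tn + cm.fn) / n
    p_e = act_pos * pred_pos + act_neg * pred_neg
    kappa = _ratio(p_o - p_e, 1.0 - p_e) if not math.isclose(p_e, 1.0) else float("nan")
    return MetricSet(
        accuracy=p_o,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        kappa=kappa,
        positive_rate_true=act_pos,
        positive_rate_predicted=pred_pos,
    )


def aggregate_bilateral(pred_left: bool | int | None, pred_right: bool | int | None) -> bool:
    """Patient-level call from two per-side calls: positive iff any side is.

    A patient is labelled negative only when both kidneys are predicted
    negative; otherwise positive (logical OR).
    """
    if pred_left is None or pred_right is None:
        raise ValueError("both side predictions are required")
    return bool(pred_left) or bool(pred_right)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equivalent to the Mann-Whitney probability that a random positive
    scores above a random negative, counting ties as 1/2.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class FoldAggregate:
    per_fold_values: tuple[float, ...]
    mean: float
    ci95_low: float
    ci95_high: float
    sd: float = field(default=float("nan"), compare=False)


def aggregate_folds(per_fold: Sequence[float], confidence: float = 0.95) -> FoldAggregate:
    """Mean of fold-specific estimates with a t-distribution CI.

    CI = mean +/- t_{(1+c)/2, k-1} * sd / sqrt(k) over the k fold values
    (k=10 in the standard protocol, df=9).
    """
    values = tuple(float(v) for v in per_fold)
    k = len(values)
    if k < 2:
        raise ValueError("need at least 2 fold values for a confidence interval")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=k - 1))
    half = tcrit * sd / math.sqrt(k)
    return FoldAggregate(values, mean, mean - half, mean + half, sd=sd)


_REPORT_ROWS = [
    ("Accuracy", "accuracy"),
    ("Sensitivity", "sensitivity"),
    ("Specificity", "specificity"),
    ("Precision", "precision"),
    ("F1-score", "f1"),
    ("Cohen's kappa", "kappa"),
]


def clinician_report(
    model_cm_by_setting: Mapping[str, ConfusionMatrix] | None = None,
    clinician_cm_by_setting: Mapping[str, ConfusionMatrix] | None = None,
    model_fold_averaged: bool = True,
    ndigits: int = 3,
) -> pd.DataFrame:
    """Metrics-by-reader comparison table.

    Columns are one per reader/setting (clinician single-side, clinician
    bilateral, model severe-side, model bilateral). Cohen's kappa is omitted
    (NaN) for fold-averaged model matrices, where per-case agreement is not
    defined.
    """
    if clinician_cm_by_setting is None:
        clinician_cm_by_setting = {
            "Clinician (single-side)": CLINICIAN_SINGLE_KIDNEY,
            "Clinician (bilateral-side)": CLINICIAN_BILATERAL,
        }
    columns: dict[str, dict[str, float]] = {}
    for name, cm in clinician_cm_by_setting.items():
        ms = compute_metrics(cm)
        columns[name] = {row: getattr(ms, attr) for row, attr in _REPORT_ROWS}
    for name, cm in (model_cm_by_setting or {}).items():
        ms = compute_metrics(cm)
        col = {row: getattr(ms, attr) for row, attr in _REPORT_ROWS}
        if model_fold_averaged:
            col["Cohen's kappa"] = float("nan")
        columns[name] = col
    frame = pd.DataFrame(columns)
    frame.index.name = "Metric"
    return frame.round(ndigits)
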