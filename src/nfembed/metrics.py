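"""Classification and regression evaluation metrics.

Classification metrics are computed directly from confusion counts
(TP, FP, TN, FN): F1 = 2TP/(2TP+FP+FN), SN = TP/(TP+FN), SP = TN/(TN+FP),
ACC, BACC = (SN+SP)/2, PREC = TP/(TP+FP), and the Matthews correlation
coefficient. AUC is the rank-based (Mann-Whitney) probability that a
random positive scores above a random negative, ties counted 1/2 —
exact for finite samples. Regression: R^2, MSE, RMSE, MAE.

Zero-denominator conventions: PREC, SN, SP and F1 evaluate to 0 when their
denominator is 0; MCC is 0 when any marginal is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

CLASSIFICATION_METRIC_ORDER = ("SN", "SP", "BACC", "ACC", "PREC", "F1", "MCC", "AUC")
REGRESSION_METRIC_ORDER = ("R2", "MSE", "RMSE", "MAE")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts are all zero")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors must have equal length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """All confusion-count metrics; AUC requires scores (see :func:`auc`)."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    mcc_den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den > 0 else 0.0
    return {
        "SN": sn,
        "SP": sp,
        "BACC": (sn + sp) / 2.0,
        "ACC": _ratio(tp + tn, tp + fp + tn + fn),
        "PREC": _ratio(tp, tp + fp),
        "F1": _ratio(2 * tp, 2 * tp + fp + fn),
        "MCC": float(mcc),
    }


def auc(scores, labels) -> float:
    """Rank-based AUC with ties counted 1/2; exact for finite samples."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """R^2, MSE, RMSE, MAE; R^2 requires non-degenerate truth variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if len(y_true) < 1:
        raise ValueError("empty input")
    resid = y_true - y_pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if len(y_true) < 2 or ss_tot == 0:
        raise ValueError("R^2 undefined: truth variance is zero")
    return {
        "R2": 1.0 - float(np.sum(resid**2)) / ss_tot,
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "MAE": float(np.mean(np.abs(resid))),
    }


def report_row(report: dict[str, float], task: str = "classification") -> str:
    """One-row TSV rendering in the conventional column order."""
    order = CLASSIFICATION_METRIC_ORDER if task == "classification" else REGRESSION_METRIC_ORDER
    cols = [k for k in order if k in report]
    return (
        "\t".join(cols) + "\n" + "\t".join(f"{report[k]:.4f}" for k in cols) + "\n"
    )
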