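"""Confusion-count metric suite for binary (micro-averaged) classification.

Counts are aggregated one-vs-rest over all classes; for a two-class task
this forces TP = TN and FP = FN, which is why accuracy, precision, recall,
specificity, F1 and NPV coincide in that setting.  Ratios are computed on
exact counts and only rounded (half-up, two decimals) for display.

The suite: accuracy, F1, precision, recall, specificity, AUC, sensitivity
(= recall), IoU, Dice, cosine similarity, Youden index
(sensitivity + specificity - 100%) and NPV, combined by an equal-weight
(1/12) weighted sum.  AUC and cosine similarity need per-sample scores and
are merged into the report from the prediction pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "UndefinedMetricError",
    "micro_confusion",
    "compute_metrics",
    "auc_rank",
    "cosine_similarity_score",
    "weighted_sum",
    "aggregate_reports",
    "round_half_up",
    "report_frame",
    "write_report",
]

METRIC_NAMES = (
    "accuracy",
    "f1",
    "precision",
    "recall",
    "specificity",
    "auc",
    "sensitivity",
    "iou",
    "dice",
    "cosine_similarity",
    "youden_index",
    "npv",
)


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. zero denominator)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Micro-aggregated TP/TN/FP/FN over all classes."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    """The 12-metric suite, each as a percentage (``None`` = undefined)."""

    accuracy: float | None = None
    f1: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    auc: float | None = None
    sensitivity: float | None = None
    iou: float | None = None
    dice: float | None = None
    cosine_similarity: float | None = None
    youden_index: float | None = None
    npv: float | None = None

    def with_scores(self, auc: float | None = None, cosine_similarity: float | None = None) -> "MetricReport":
        """Merge the score-based metrics computed in the prediction pathway."""
        out = self
        if auc is not None:
            out = replace(out, auc=auc)
        if cosine_similarity is not None:
            out = replace(out, cosine_similarity=cosine_similarity)
        return out

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def micro_confusion(true_labels: Sequence, predicted_labels: Sequence, n_classes: int) -> ConfusionCounts:
    """Sum one-vs-rest TP/TN/FP/FN over all classes.

    For two classes the sums are symmetric: TP = TN and FP = FN.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = int(cm.sum())
    tp = int(np.trace(cm))
    fn = int((cm.sum(axis=1) - np.diag(cm)).sum())
    fp = int((cm.sum(axis=0) - np.diag(cm)).sum())
    # per class k: TN_k = total - TP_k - FP_k - FN_k; summed over classes
    tn = n_classes * total - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Count-based metrics (AUC and cosine similarity excluded).

    Any metric with a zero denominator comes back as ``None`` rather than
    raising, so a degenerate evaluation does not abort a pipeline.
    """
    if counts.total == 0:
        raise UndefinedMetricError("empty confusion counts")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    accuracy = _ratio(tp + tn, counts.total)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    npv = _ratio(tn, tn + fn)
    dice = _ratio(2 * tp, 2 * tp + fp + fn)
    iou = _ratio(tp, tp + fp + fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    youden = None
    if specificity is not None and recall is not None:
        youden = specificity + recall - 100.0
    return MetricReport(
        accuracy=accuracy,
        f1=f1,
        precision=precision,
        recall=recall,
        specificity=specificity,
        sensitivity=recall,
        iou=iou,
        dice=dice,
        youden_index=youden,
        npv=npv,
    )


def auc_rank(true_labels: Sequence[int], scores: Sequence[float]) -> float:
    """ROC AUC as a percentage via the rank-sum (Mann-Whitney) statistic.

    Ties contribute 1/2.  Requires both classes to be present.
    """
    y = np.asarray(true_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties at 1/2
    rank_sum = ranks[y == 1].sum()
    auc = (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return 100.0 * auc


def cosine_similarity_score(one_hot_truth: np.ndarray, predicted_probabilities: np.ndarray) -> float:
    """Mean per-sample cosine between truth and prediction vectors, as a percentage."""
    y = np.asarray(one_hot_truth, dtype=float)
    p = np.asarray(predicted_probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("truth and prediction matrices must have matching shapes")
    ny = np.linalg.norm(y, axis=1)
    np_ = np.linalg.norm(p, axis=1)
    if np.any(ny == 0) or np.any(np_ == 0):
        raise UndefinedMetricError("zero-norm row in cosine similarity input")
    cos = (y * p).sum(axis=1) / (ny * np_)
    return 100.0 * float(cos.mean())


def weighted_sum(report: MetricReport) -> float:
    """Equal-weight (1/12) mean of the 12 metrics."""
    values = [getattr(report, name) for name in METRIC_NAMES]
    if any(v is None for v in values):
        missing = [n for n, v in zip(METRIC_NAMES, values) if v is None]
        raise UndefinedMetricError(f"weighted sum undefined; missing metrics: {missing}")
    return float(sum(values)) / 12.0


def aggregate_reports(reports: Sequence[MetricReport]) -> MetricReport:
    """Per-metric arithmetic mean across reports (e.g. across models).

    A metric that is undefined in any report is undefined in the mean.
    """
    if len(reports) == 0:
        raise ValueError("need at least one report to aggregate")
    out = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        out[name] = None if any(v is None for v in vals) else float(np.mean(vals))
    return MetricReport(**out)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Half-up rounding used for presentation (table formatting)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def report_frame(reports: dict[str, MetricReport], include_ws: bool = True) -> pd.DataFrame:
    """Table-shaped frame: metrics as rows, one column per model/run."""
    rows = {name: [] for name in METRIC_NAMES}
    ws_row = []
    for rep in reports.values():
        for name in METRIC_NAMES:
            v = getattr(rep, name)
            rows[name].append(None if v is None else round_half_up(v))
        if include_ws:
            try:
                ws_row.append(round_half_up(weighted_sum(rep)))
            except UndefinedMetricError:
                ws_row.append(None)
    data = dict(rows)
    if include_ws:
        data["weighted_sum"] = ws_row
    return pd.DataFrame(data, index=list(reports.keys())).T


def write_report(reports: dict[str, MetricReport], csv_path=None, json_path=None) -> pd.DataFrame:
    frame = report_frame(reports)
    if csv_path is not None:
        frame.to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({k: v.to_dict() for k, v in reports.items()}, fh, indent=2)
    return frame
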