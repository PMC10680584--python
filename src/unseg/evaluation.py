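"""Instance-segmentation evaluation: IoU matching, F1 scores and curves.

Predicted and ground-truth objects are matched one-to-one at an IoU
threshold (pairs with IoU above the threshold accepted greedily in
descending IoU); the F1 score is ``2TP / (2TP + FP + FN)``. Sweeping the
threshold gives an F1 curve, which is non-increasing in the threshold;
dataset-level results are summarized by pointwise median curves with a
percentile band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("unseg")

__all__ = [
    "MatchResult",
    "F1Curve",
    "iou_table",
    "match_objects",
    "f1_score",
    "f1_curve",
    "median_f1_over_dataset",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: np.ndarray = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass
class MatchResult:
    """Outcome of one-to-one object matching at a fixed IoU threshold."""

    tp: int
    fp: int
    fn: int
    iou_threshold: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp != len(self.pairs):
            raise ValueError("TP must equal the number of matched pairs")


@dataclass
class F1Curve:
    """F1 values over a strictly increasing IoU-threshold grid."""

    thresholds: np.ndarray
    f1_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        f = np.asarray(self.f1_values, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("thresholds and f1 values must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds, self.f1_values = t, f


def iou_table(pred: np.ndarray, gt: np.ndarray) -> pd.DataFrame:
    """All overlapping (gt_id, pred_id) pairs with their IoU."""
    pred = np.asarray(pred).ravel()
    gt = np.asarray(gt).ravel()
    if pred.shape != gt.shape:
        raise ValueError("label maps must share a shape")
    both = (pred > 0) & (gt > 0)
    pred_areas = np.bincount(pred[pred > 0])
    gt_areas = np.bincount(gt[gt > 0])
    if not both.any():
        return pd.DataFrame(columns=["gt_id", "pred_id", "iou"])
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True
    )
    inter = counts.astype(float)
    union = gt_areas[pairs[0]] + pred_areas[pairs[1]] - inter
    return pd.DataFrame({
        "gt_id": pairs[0].astype(int),
        "pred_id": pairs[1].astype(int),
        "iou": inter / union,
    })


def _match_from_table(table: pd.DataFrame, n_gt: int, n_pred: int,
                      threshold: float) -> MatchResult:
    cand = table[table["iou"] > threshold]
    cand = cand.sort_values(["iou", "gt_id", "pred_id"],
                            ascending=[False, True, True])
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for row in cand.itertuples(index=False):
        if row.gt_id in used_gt or row.pred_id in used_pred:
            continue
        used_gt.add(row.gt_id)
        used_pred.add(row.pred_id)
        pairs.append((int(row.gt_id), int(row.pred_id), float(row.iou)))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=n_pred - tp, fn=n_gt - tp,
                       iou_threshold=threshold, pairs=pairs)


def match_objects(pred: np.ndarray, gt: np.ndarray,
                  iou_threshold: float) -> MatchResult:
    """One-to-one matching of predicted to ground-truth objects.

    Pairs with IoU strictly above the threshold are accepted greedily in
    descending IoU (ties broken by smaller gt id, then pred id); every
    object participates in at most one match. The counts satisfy
    ``TP + FN = #gt objects`` and ``TP + FP = #predicted objects``.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must lie in (0, 1]")
    table = iou_table(pred, gt)
    n_gt = int(np.unique(gt[gt > 0]).size)
    n_pred = int(np.unique(pred[pred > 0]).size)
    return _match_from_table(table, n_gt, n_pred, iou_threshold)


def f1_score(tp: int, fp: int, fn: int) -> float:
    """``2TP / (2TP + FP + FN)``; empty-vs-empty defined as 1."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == fp == fn == 0:
        logger.warning("f1_score on empty-vs-empty comparison; returning 1.0")
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def f1_curve(pred: np.ndarray, gt: np.ndarray,
             thresholds: np.ndarray | None = None) -> F1Curve:
    """F1 as a function of the IoU threshold (non-increasing)."""
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(
        thresholds, dtype=float)
    table = iou_table(pred, gt)
    n_gt = int(np.unique(gt[gt > 0]).size)
    n_pred = int(np.unique(pred[pred > 0]).size)
    values = []
    for t in thresholds:
        m = _match_from_table(table, n_gt, n_pred, float(t))
        values.append(f1_score(m.tp, m.fp, m.fn))
    return F1Curve(thresholds=thresholds, f1_values=np.asarray(values))


def median_f1_over_dataset(
    curves: list[F1Curve],
    band: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Pointwise median F1 curve with a percentile band over a dataset."""
    if not curves:
        raise ValueError("at least one curve required")
    grid = curves[0].thresholds
    for c in curves[1:]:
        if c.thresholds.shape != grid.shape or not np.allclose(c.thresholds, grid):
            raise ValueError("curves must share the threshold grid")
    stack = np.stack([c.f1_values for c in curves])
    lo, hi = np.percentile(stack, band, axis=0)
    return pd.DataFrame({
        "threshold": grid,
        "median_f1": np.median(stack, axis=0),
        "band_low": lo,
        "band_high": hi,
    })
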