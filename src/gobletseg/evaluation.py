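"""Pixel-level segmentation metrics and precision-recall analysis.

Metrics follow the standard confusion-matrix definitions:

    recall (TPR)  = TP / (TP + FN)
    precision     = TP / (TP + FP)
    FPR           = 1 - TN / (TN + FP)
    IoU           = TP / (TP + FP + FN)
    Dice          = 2 TP / (2 TP + FP + FN)

Dice and IoU are linked by dice = 2*iou/(1+iou). When both prediction and
ground truth are empty, the overlap metrics are defined as 1 (the pair
agrees perfectly) and the report is flagged degenerate.
"""

from __future__ import annotations

import numpy as np

from .types import ConfusionCounts, MetricReport, as_label_mask

__all__ = ["confusion", "metrics_from_counts", "pr_curve", "aggregate_runs"]


def confusion(pred_mask: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts for a co-registered mask pair."""
    p = as_label_mask(pred_mask)
    g = as_label_mask(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, empty_value: float = 1.0) -> float:
    return num / den if den > 0 else empty_value


def metrics_from_counts(c: ConfusionCounts) -> MetricReport:
    """Dice, IoU, recall, precision and FPR from confusion counts."""
    degenerate = (c.tp + c.fp + c.fn) == 0
    return MetricReport(
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        recall=_ratio(c.tp, c.tp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        fpr=1.0 - _ratio(c.tn, c.tn + c.fp, empty_value=1.0),
        degenerate=degenerate,
    )


def pr_curve(prob: np.ndarray, gt: np.ndarray,
             thresholds: np.ndarray | None = None):
    """Precision-recall curve over binarization thresholds, with AP.

    Returns ``(points, ap)`` where ``points`` is a list of
    ``(threshold, recall, precision)`` and ``ap`` is the area under the
    precision-recall curve by trapezoidal integration over recall
    (true negatives play no role). An empty ground truth is flagged by
    returning ``ap = nan``.
    """
    prob = np.asarray(prob, dtype=np.float64)
    g = as_label_mask(gt)
    if prob.shape != g.shape:
        raise ValueError("probability map and ground truth shapes differ")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 256)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(thresholds) < 0) or thresholds.min() < 0 or thresholds.max() > 1:
        raise ValueError("thresholds must be sorted and within [0, 1]")
    n_pos = int(g.sum())
    points = []
    for t in thresholds:
        c = confusion(prob > t, g)
        m = metrics_from_counts(c)
        points.append((float(t), m.recall, m.precision))
    if n_pos == 0:
        return points, float("nan")
    # integrate precision d(recall); recall decreases with threshold
    rec = np.array([p[1] for p in points])
    prec = np.array([p[2] for p in points])
    order = np.argsort(rec, kind="stable")
    rec, prec = rec[order], prec[order]
    # anchor at recall 0 with the precision of the smallest positive recall
    if rec[0] > 0:
        rec = np.concatenate([[0.0], rec])
        prec = np.concatenate([[prec[0]], prec])
    ap = float(np.trapezoid(prec, rec))
    return points, ap


def aggregate_runs(reports: list[MetricReport]):
    """Per-metric sample mean and sd over repeated evaluation runs."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to aggregate")
    out = {}
    keys = ["dice", "iou", "recall", "precision", "fpr"]
    if all(r.ap is not None for r in reports):
        keys.append("ap")
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=np.float64)
        out[k] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
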