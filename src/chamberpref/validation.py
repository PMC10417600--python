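"""Count-level detector validation, average precision, and sample sizing.

The detector is validated at the count level: for a sample of synchronized
scenes, manually established true bird counts are compared with predicted
counts in a square confusion matrix, from which exact-count accuracy and
the over-count-by-one rate are read off.  Box-level quality is measured by
single-class average precision (area under the precision-recall curve after
IoU-thresholded greedy matching).  The size of the manual sample is chosen
with the finite-population sample-size formula

    n = p (1-p) Z^2 N / ( eps^2 (N-1) + Z^2 p (1-p) ),

rounded up, where N is the population of frames, p the expected proportion,
Z the normal quantile of the confidence level and eps the margin of error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountConfusion",
    "APResult",
    "count_confusion",
    "count_accuracy",
    "overcount_rate",
    "sample_size",
    "z_for_confidence",
    "iou",
    "average_precision",
]


@dataclass
class CountConfusion:
    """Square matrix of true count (rows) vs predicted count (columns)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (m < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        self.matrix = m.astype(int)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def c_max(self) -> int:
        return self.matrix.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        labels = list(range(self.c_max + 1))
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(labels, name="true"),
            columns=pd.Index(labels, name="predicted"),
        )


def count_confusion(
    true_counts: Sequence[int],
    predicted_counts: Sequence[int],
    c_max: int | None = None,
) -> CountConfusion:
    """Tally aligned true/predicted count sequences into a confusion matrix."""
    t = np.asarray(true_counts, dtype=int)
    p = np.asarray(predicted_counts, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} true vs {p.shape} predicted")
    if (t < 0).any() or (p < 0).any():
        raise ValueError("counts must be non-negative")
    hi = int(max(t.max(initial=0), p.max(initial=0)))
    if c_max is None:
        c_max = hi
    elif c_max < hi:
        raise ValueError(f"c_max={c_max} smaller than observed count {hi}")
    m = np.zeros((c_max + 1, c_max + 1), dtype=int)
    np.add.at(m, (t, p), 1)
    return CountConfusion(m)


def count_accuracy(confusion: CountConfusion) -> float:
    """Percent of scenes with exactly the right count: 100 x trace / total.

    Returned unrounded; report to one decimal place.
    """
    if confusion.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(confusion.matrix)) / confusion.total


def overcount_rate(confusion: CountConfusion) -> float:
    """Percent of scenes over-counted by exactly one (predicted = true + 1).

    Returned unrounded; report to two decimal places.
    """
    if confusion.total == 0:
        raise ValueError("empty confusion matrix")
    super_diag = float(np.trace(confusion.matrix, offset=1))
    return 100.0 * super_diag / confusion.total


def z_for_confidence(confidence: float) -> float:
    """Two-sided normal quantile for a confidence level, e.g. 0.99 -> 2.576."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    return float(stats.norm.ppf(1 - (1 - confidence) / 2))


def sample_size(
    N: float,
    p: float = 0.5,
    eps: float = 0.04,
    Z: float | None = None,
    confidence: float | None = None,
) -> int:
    """Finite-population sample size, rounded up to a whole number of frames.

    Either ``Z`` (normal quantile) or ``confidence`` must be given.  The
    result is largest at p = 0.5 and grows with N and Z, shrinks with eps.
    """
    if Z is None:
        if confidence is None:
            raise ValueError("provide either Z or confidence")
        Z = z_for_confidence(confidence)
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if not eps > 0:
        raise ValueError("margin of error eps must be positive")
    if N < 1:
        raise ValueError("population size N must be at least 1")
    num = p * (1 - p) * Z**2 * N
    den = eps**2 * (N - 1) + Z**2 * p * (1 - p)
    return math.ceil(num / den)


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------


@dataclass
class APResult:
    """Single-class average precision; with one category mAP = AP_1."""

    ap_per_category: list[float]
    iou_threshold: float

    @property
    def mAP(self) -> float:
        return float(np.mean(self.ap_per_category))

    @property
    def n_categories(self) -> int:
        return len(self.ap_per_category)


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection over union of two (x_min, y_min, x_max, y_max) boxes."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def average_precision(
    predictions: dict[int, list[tuple[Sequence[float], float]]],
    ground_truth: dict[int, list[Sequence[float]]],
    iou_threshold: float = 0.5,
) -> APResult:
    """Average precision of box predictions against ground truth.

    ``predictions`` maps image id to (box, confidence score) pairs and
    ``ground_truth`` maps image id to boxes.  Predictions are processed in
    descending score order and greedily matched to the not-yet-matched
    ground-truth box of the same image with the highest IoU, counting a
    true positive when that IoU reaches the threshold.  AP is the area
    under the precision-recall curve with the all-point (continuous)
    interpolation: precision is replaced by its running maximum from the
    right before integrating over recall.

    Raises if there is no ground-truth box anywhere (recall undefined).
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must be in (0, 1]")
    n_gt = sum(len(v) for v in ground_truth.values())
    if n_gt == 0:
        raise ValueError("average precision undefined without ground-truth boxes")

    flat = [
        (score, img, box)
        for img, preds in predictions.items()
        for box, score in preds
    ]
    # stable sort, descending score; ties keep insertion order
    flat.sort(key=lambda t: -t[0])
    matched: dict[int, set[int]] = {img: set() for img in ground_truth}
    tp = np.zeros(len(flat))
    for k, (score, img, box) in enumerate(flat):
        gts = ground_truth.get(img, [])
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if j in matched.setdefault(img, set()):
                continue
            v = iou(box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[k] = 1.0
            matched[img].add(best_j)
    if len(flat) == 0:
        return APResult(ap_per_category=[0.0], iou_threshold=iou_threshold)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope (running max from the right), then integrate
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    ap = float(np.sum((r[1:] - r[:-1]) * env))
    return APResult(ap_per_category=[ap], iou_threshold=iou_threshold)
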