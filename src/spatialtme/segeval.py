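"""Nucleus-segmentation evaluation by IoU-based instance matching.

A predicted label mask is scored against a ground-truth label mask: every
ground-truth nucleus is paired with the as-yet-unmatched prediction of
maximal intersection-over-union, pairs are kept iff IoU > 0.6 (strict),
and the remaining ground-truth / predicted objects count as false
negatives / false positives. Detection coverage, precision, recall, the
F1 score and binary-foreground pixel accuracy summarise the result.

Because any two instances with IoU > 0.5 must claim a majority of each
other's pixels, matches above the 0.6 threshold are mutually exclusive and
the greedy descending-IoU pairing coincides with the optimal assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_IOU_THRESHOLD = 0.6


@dataclass
class MatchResult:
    """Instance-matching outcome and derived metrics."""

    matches: list = field(default_factory=list)  # (gt_label, pred_label, iou)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    detection_coverage: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    pa: float = float("nan")


def iou_matrix(gt_mask: np.ndarray, pred_mask: np.ndarray):
    """Pairwise IoU between every GT and predicted instance.

    Returns ``(gt_labels, pred_labels, iou)`` where ``iou`` has shape
    ``(len(gt_labels), len(pred_labels))``.
    """
    gt = np.asarray(gt_mask)
    pred = np.asarray(pred_mask)
    if gt.shape != pred.shape:
        raise ValueError("label masks must share dimensions")
    gt_labels = np.unique(gt[gt > 0])
    pred_labels = np.unique(pred[pred > 0])
    areas_gt = {g: int(np.count_nonzero(gt == g)) for g in gt_labels}
    areas_pred = {p: int(np.count_nonzero(pred == p)) for p in pred_labels}

    both = (gt > 0) & (pred > 0)
    pairs, inter = np.unique(
        np.column_stack([gt[both], pred[both]]), axis=0, return_counts=True
    ) if both.any() else (np.empty((0, 2), dtype=gt.dtype), np.empty(0, dtype=int))

    gi = {g: k for k, g in enumerate(gt_labels)}
    pi = {p: k for k, p in enumerate(pred_labels)}
    iou = np.zeros((len(gt_labels), len(pred_labels)))
    for (g, p), it in zip(pairs, inter):
        union = areas_gt[g] + areas_pred[p] - it
        iou[gi[g], pi[p]] = it / union
    return gt_labels, pred_labels, iou


def match_nuclei(
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Match predicted nuclei to ground truth and compute all metrics.

    Greedy one-to-one matching in descending IoU order (ties broken by the
    smaller GT label, then the smaller predicted label); a pair is kept
    iff its IoU is strictly greater than ``iou_threshold``.
    """
    gt_labels, pred_labels, iou = iou_matrix(gt_mask, pred_mask)

    order = []
    for a in range(iou.shape[0]):
        for b in range(iou.shape[1]):
            if iou[a, b] > iou_threshold:
                order.append((-iou[a, b], gt_labels[a], pred_labels[b], a, b))
    order.sort()
    used_gt: set = set()
    used_pred: set = set()
    matches = []
    for neg_iou, g, p, a, b in order:
        if a in used_gt or b in used_pred:
            continue
        used_gt.add(a)
        used_pred.add(b)
        matches.append((int(g), int(p), -neg_iou))

    tp = len(matches)
    fn = len(gt_labels) - tp
    fp = len(pred_labels) - tp
    precision, recall, f1 = f1_score(tp, fp, fn)
    res = MatchResult(
        matches=matches,
        tp=tp,
        fp=fp,
        fn=fn,
        detection_coverage=detection_coverage(tp, len(gt_labels))
        if len(gt_labels)
        else float("nan"),
        precision=precision,
        recall=recall,
        f1=f1,
        pa=pixel_accuracy(gt_mask, pred_mask),
    )
    return res


def f1_score(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, F1) from instance counts.

    F1 = 2 * precision * recall / (precision + recall); all three metrics
    are defined as 0 (with a warning) when every count is zero.
    """
    if tp == 0 and fp == 0 and fn == 0:
        warnings.warn("no instances at all; metrics defined as 0", stacklevel=2)
        return 0.0, 0.0, 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def pixel_accuracy(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """Fraction of pixels agreeing on binary foreground/background."""
    gt = np.asarray(gt_mask)
    pred = np.asarray(pred_mask)
    if gt.shape != pred.shape:
        raise ValueError("masks must share dimensions")
    return float(np.mean((gt > 0) == (pred > 0)))


def detection_coverage(n_matched: int, n_gt: int) -> float:
    """Matched nuclei as a fraction of ground-truth nuclei."""
    if n_gt <= 0:
        raise ValueError("detection coverage is undefined for zero GT nuclei")
    return n_matched / n_gt
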