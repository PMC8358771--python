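"""Detection-quality metrics: IoU matching, average precision, error rate.

The evaluation protocol is the standard object-detection benchmark:
predictions are ranked by confidence; each prediction greedily claims
the unmatched ground-truth box of highest IoU provided that IoU meets
the threshold; precision-recall is accumulated over the ranking and
average precision (AP) is the area under the interpolated PR curve.
With a single category, mean average precision (mAP) equals AP.

``interpolation="all_points"`` (default) integrates the precision
envelope over all recall change-points; ``"coco101"`` averages the
envelope at 101 evenly spaced recall values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import BoundingBox

__all__ = [
    "MatchResult",
    "iou",
    "match_detections",
    "average_precision",
    "mean_ap",
    "count_error_rate",
    "precision_recall_points",
]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    if ix <= 0:
        return 0.0
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching between predictions and ground truth."""

    true_positives: int
    false_positives: int
    false_negatives: int
    #: (prediction index, ground-truth index, IoU) per match
    matches: tuple[tuple[int, int, float], ...]


def _ranked_indices(predictions: Sequence[BoundingBox]) -> list[int]:
    # score descending; ties by smaller area then lower x (deterministic)
    return sorted(range(len(predictions)),
                  key=lambda i: (-(predictions[i].score or 0.0),
                                 predictions[i].area, predictions[i].xmin))


def match_detections(predictions: Sequence[BoundingBox],
                     ground_truth: Sequence[BoundingBox],
                     iou_threshold: float) -> MatchResult:
    """Greedy score-ordered matching at an IoU threshold.

    Predictions are processed by descending score; each claims the
    still-unmatched ground-truth box with the highest IoU if that IoU is
    >= the threshold, otherwise it is a false positive.
    """
    taken: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for pi in _ranked_indices(predictions):
        best_gi, best_iou = -1, 0.0
        for gi, g in enumerate(ground_truth):
            if gi in taken:
                continue
            v = iou(predictions[pi], g)
            if v > best_iou:
                best_gi, best_iou = gi, v
        if best_gi >= 0 and best_iou >= iou_threshold:
            taken.add(best_gi)
            matches.append((pi, best_gi, best_iou))
    tp = len(matches)
    return MatchResult(
        true_positives=tp,
        false_positives=len(predictions) - tp,
        false_negatives=len(ground_truth) - tp,
        matches=tuple(matches),
    )


def _pooled_tp_flags(predictions_by_image: Mapping[str, Sequence[BoundingBox]],
                     ground_truth_by_image: Mapping[str, Sequence[BoundingBox]],
                     iou_threshold: float
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    """Rank predictions across images; per-rank TP flags and scores."""
    entries: list[tuple[float, float, float, str, int]] = []
    for iid, preds in predictions_by_image.items():
        for k, p in enumerate(preds):
            entries.append((-(p.score or 0.0), p.area, p.xmin, iid, k))
    entries.sort()
    taken: dict[str, set[int]] = {iid: set()
                                  for iid in ground_truth_by_image}
    flags = np.zeros(len(entries), dtype=bool)
    scores = np.empty(len(entries))
    for rank, (neg_score, _, _, iid, k) in enumerate(entries):
        scores[rank] = -neg_score
        p = predictions_by_image[iid][k]
        gts = ground_truth_by_image.get(iid, ())
        used = taken.setdefault(iid, set())
        best_gi, best_iou = -1, 0.0
        for gi, g in enumerate(gts):
            if gi in used:
                continue
            v = iou(p, g)
            if v > best_iou:
                best_gi, best_iou = gi, v
        if best_gi >= 0 and best_iou >= iou_threshold:
            used.add(best_gi)
            flags[rank] = True
    n_gt = sum(len(g) for g in ground_truth_by_image.values())
    return flags, scores, n_gt


def _ap_from_flags(flags: np.ndarray, n_gt: int,
                   interpolation: str) -> float:
    if n_gt == 0:
        return float("nan")
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: running max from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "all_points":
        r = np.concatenate(([0.0], recall))
        return float(np.sum((r[1:] - r[:-1]) * envelope))
    if interpolation == "coco101":
        grid = np.linspace(0.0, 1.0, 101)
        interp = np.zeros_like(grid)
        for i, g in enumerate(grid):
            mask = recall >= g
            interp[i] = envelope[mask][0] if mask.any() else 0.0
        return float(interp.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


def average_precision(predictions: Sequence[BoundingBox],
                      ground_truth: Sequence[BoundingBox],
                      iou_threshold: float,
                      interpolation: str = "all_points") -> float:
    """AP of one image's predictions; NaN when there is no ground truth."""
    flags, _, n_gt = _pooled_tp_flags({"_": predictions}, {"_": ground_truth},
                                      iou_threshold)
    return _ap_from_flags(flags, n_gt, interpolation)


def mean_ap(predictions_by_image: Mapping[str, Sequence[BoundingBox]],
            ground_truth_by_image: Mapping[str, Sequence[BoundingBox]],
            thresholds: Sequence[float] = (0.3, 0.5),
            interpolation: str = "all_points") -> dict[float, float]:
    """mAP per IoU threshold, pooled over all images.

    Predictions from every image are ranked together by score; AP is
    computed on the pooled ranking (single-category evaluation, so
    mAP = AP).
    """
    out: dict[float, float] = {}
    for thr in thresholds:
        flags, _, n_gt = _pooled_tp_flags(predictions_by_image,
                                          ground_truth_by_image, thr)
        out[thr] = _ap_from_flags(flags, n_gt, interpolation)
    return out


def precision_recall_points(
        predictions_by_image: Mapping[str, Sequence[BoundingBox]],
        ground_truth_by_image: Mapping[str, Sequence[BoundingBox]],
        iou_threshold: float) -> np.ndarray:
    """(score, recall, precision) per rank of the pooled PR curve."""
    flags, scores, n_gt = _pooled_tp_flags(predictions_by_image,
                                           ground_truth_by_image,
                                           iou_threshold)
    if flags.size == 0 or n_gt == 0:
        return np.empty((0, 3))
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    return np.column_stack([scores, tp / n_gt, tp / (tp + fp)])


def count_error_rate(auto: float, manual: float) -> float:
    """Percent deviation of an automated count from the manual truth."""
    if manual <= 0:
        raise ValueError(f"manual count must be > 0, got {manual}")
    return 100.0 * abs(auto - manual) / manual
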