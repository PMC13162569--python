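"""Pixel- and instance-level segmentation evaluation.

Pixel metrics follow the standard confusion-count formulas

    Dice      = 2 TP / (2 TP + FP + FN)
    IoU       = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)

with a small epsilon (1e-8) added to every denominator so empty masks score
0 rather than dividing by zero.  Per-class summaries report mean, median and
sample standard deviation of per-image records ("mean (median) ± SD").

Instance metrics use COCO-style greedy matching: predictions sorted by
confidence, each matched to the unmatched ground-truth instance of highest
mask IoU at or above the threshold; AP by 101-point precision
interpolation; mAP50-95 averages thresholds 0.50..0.95 in steps of 0.05.
The composite model-tuning objective is 0.7*F1 + 0.3*mAP50-95, weighting
segmentation detection performance over strict boundary overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import PolygonInstance, rasterize
from .model import BinaryMask, ColposegError

EPSILON = 1e-8
IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
RECALL_POINTS = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricRecord:
    image_id: int
    class_name: str
    dice: float
    iou: float
    precision: float
    recall: float


@dataclass(frozen=True)
class MetricStats:
    mean: float
    median: float
    sd: float


@dataclass(frozen=True)
class ClassSummary:
    """Per-class spread of per-image pixel metrics, Table-style mean (median) ± SD."""

    n_images: int
    dice: MetricStats
    iou: MetricStats
    precision: MetricStats
    recall: MetricStats

    def format_row(self) -> str:
        cells = [
            f"{s.mean:.2f} ({s.median:.2f}) ± {s.sd:.2f}"
            for s in (self.dice, self.iou, self.precision, self.recall)
        ]
        return "\t".join(cells)


@dataclass
class InstancePrediction:
    """One predicted instance: mask (binary or polygon) plus confidence."""

    image_id: int
    class_name: str
    mask: Union[BinaryMask, PolygonInstance]
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    def binary_mask(self, width_px: int, height_px: int) -> BinaryMask:
        if isinstance(self.mask, BinaryMask):
            return self.mask
        return rasterize(self.mask, width_px, height_px)


@dataclass(frozen=True)
class ApResult:
    per_threshold: dict[float, float]
    map50: float
    map50_95: float


# ---------------------------------------------------------------------------
# pixel level


def pixel_confusion(pred: BinaryMask, gt: BinaryMask) -> PixelConfusion:
    if pred.membership.shape != gt.membership.shape:
        raise ColposegError(
            f"frame mismatch: {pred.membership.shape} vs {gt.membership.shape}"
        )
    p, g = pred.membership, gt.membership
    return PixelConfusion(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def dice(c: PixelConfusion) -> float:
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn + EPSILON)


def iou(c: PixelConfusion) -> float:
    return c.tp / (c.tp + c.fp + c.fn + EPSILON)


def precision(c: PixelConfusion) -> float:
    return c.tp / (c.tp + c.fp + EPSILON)


def recall(c: PixelConfusion) -> float:
    return c.tp / (c.tp + c.fn + EPSILON)


def evaluate_image(
    preds: Sequence[InstancePrediction],
    gt_masks: Sequence[BinaryMask],
    class_name: str,
    image_id: int = 0,
    width_px: Optional[int] = None,
    height_px: Optional[int] = None,
) -> MetricRecord:
    """Class-level pixel metrics for one image.

    Both sides are collapsed to the union of their instances before the
    confusion is computed; an image with ground truth but no prediction
    scores zero (the model omitted the mask entirely).
    """
    if gt_masks:
        height_px, width_px = gt_masks[0].membership.shape
    if width_px is None or height_px is None:
        raise ColposegError("frame size required when there is no ground truth")
    gt_union = np.zeros((height_px, width_px), dtype=bool)
    for m in gt_masks:
        gt_union |= m.membership
    pred_union = np.zeros_like(gt_union)
    for p in preds:
        if p.class_name == class_name:
            pred_union |= p.binary_mask(width_px, height_px).membership
    c = pixel_confusion(BinaryMask(pred_union), BinaryMask(gt_union))
    return MetricRecord(image_id, class_name, dice(c), iou(c), precision(c), recall(c))


def summarize(records: Sequence[MetricRecord]) -> ClassSummary:
    """Mean / median / sample SD (n-1) of each metric over the records."""
    if not records:
        raise ColposegError("cannot summarize zero records")

    def stats(values: list[float]) -> MetricStats:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return MetricStats(float(arr.mean()), float(np.median(arr)), sd)

    return ClassSummary(
        n_images=len(records),
        dice=stats([r.dice for r in records]),
        iou=stats([r.iou for r in records]),
        precision=stats([r.precision for r in records]),
        recall=stats([r.recall for r in records]),
    )


# ---------------------------------------------------------------------------
# instance level


@dataclass
class _MatchSet:
    """Predictions in confidence order with their per-GT mask IoUs."""

    confidences: np.ndarray  # (P,) sorted descending
    iou_matrix: np.ndarray  # (P, G)
    gt_image: np.ndarray  # (G,) image id per GT
    pred_image: np.ndarray  # (P,) image id per prediction


def _mask_iou(a: BinaryMask, b: BinaryMask) -> float:
    inter = int(np.count_nonzero(a.membership & b.membership))
    union = int(np.count_nonzero(a.membership | b.membership))
    return inter / union if union else 0.0


def _prepare(
    preds: Sequence[InstancePrediction],
    gts: Sequence[tuple[int, BinaryMask]],
    frame: tuple[int, int],
) -> _MatchSet:
    width_px, height_px = frame
    order = sorted(
        range(len(preds)), key=lambda i: (-preds[i].confidence, preds[i].image_id, i)
    )
    conf = np.array([preds[i].confidence for i in order], dtype=float)
    pred_image = np.array([preds[i].image_id for i in order], dtype=int)
    gt_image = np.array([img for img, _ in gts], dtype=int)
    iou_matrix = np.zeros((len(order), len(gts)), dtype=float)
    for row, i in enumerate(order):
        pm = preds[i].binary_mask(width_px, height_px)
        for col, (img, gm) in enumerate(gts):
            if img == preds[i].image_id:
                iou_matrix[row, col] = _mask_iou(pm, gm)
    return _MatchSet(conf, iou_matrix, gt_image, pred_image)


def _greedy_match(ms: _MatchSet, threshold: float, n_preds: Optional[int] = None) -> np.ndarray:
    """Greedy confidence-ordered matching; returns bool TP flags per prediction."""
    n = len(ms.confidences) if n_preds is None else n_preds
    taken = np.zeros(ms.iou_matrix.shape[1], dtype=bool)
    tp = np.zeros(n, dtype=bool)
    for i in range(n):
        ious = ms.iou_matrix[i].copy()
        ious[taken] = -1.0
        if ious.size == 0:
            continue
        j = int(np.argmax(ious))
        if ious[j] >= threshold:
            taken[j] = True
            tp[i] = True
    return tp


def _average_precision(tp_flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from confidence-ordered TP flags."""
    if n_gt == 0:
        return 0.0
    if tp_flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recalls = tp_cum / n_gt
    precisions = tp_cum / (tp_cum + fp_cum)
    # precision envelope: best precision at any recall >= r
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    ap = 0.0
    for r in RECALL_POINTS:
        idx = np.searchsorted(recalls, r, side="left")
        ap += env[idx] if idx < len(env) else 0.0
    return ap / len(RECALL_POINTS)


def mask_map(
    preds: Sequence[InstancePrediction],
    gts: Sequence[tuple[int, BinaryMask]],
    frame: tuple[int, int],
) -> ApResult:
    """Mask mAP over IoU thresholds 0.50..0.95 (COCO-style, single class).

    ``gts`` are ``(image_id, mask)`` pairs.  With no ground truth and no
    predictions AP is defined as 0.
    """
    ms = _prepare(preds, gts, frame)
    per_threshold = {}
    for t in IOU_THRESHOLDS:
        tp_flags = _greedy_match(ms, t)
        per_threshold[float(t)] = _average_precision(tp_flags, len(gts))
    aps = list(per_threshold.values())
    return ApResult(per_threshold, per_threshold[0.5], float(np.mean(aps)))


def instance_f1(
    preds: Sequence[InstancePrediction],
    gts: Sequence[tuple[int, BinaryMask]],
    frame: tuple[int, int],
    iou_threshold: float = 0.5,
) -> float:
    """Instance-level F1 at the confidence cutoff that maximizes it.

    Greedy matching at ``iou_threshold``; every observed confidence is tried
    as the cutoff (plus the empty prediction set) and the best F1 returned.
    """
    ms = _prepare(preds, gts, frame)
    n_gt = len(gts)
    best = 0.0
    tp_flags = _greedy_match(ms, iou_threshold)
    for k in range(len(tp_flags) + 1):
        # top-k predictions kept; greedy prefix matching equals full greedy
        # restricted to the prefix because matches are assigned in order
        tp = int(tp_flags[:k].sum())
        p = tp / k if k else 0.0
        r = tp / n_gt if n_gt else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        best = max(best, f1)
    return best


def composite_objective(f1: float, map50_95: float) -> float:
    """Hyperparameter-tuning objective: 0.7 * F1 + 0.3 * mAP50-95."""
    if not (0.0 <= f1 <= 1.0 and 0.0 <= map50_95 <= 1.0):
        raise ValueError("both components must lie in [0, 1]")
    return 0.7 * f1 + 0.3 * map50_95
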