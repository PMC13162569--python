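"""Pixel and instance evaluation: formula identities, matching, AP oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colposeg import BinaryMask
from colposeg.metrics import (
    IOU_THRESHOLDS,
    RECALL_POINTS,
    InstancePrediction,
    MetricRecord,
    PixelConfusion,
    composite_objective,
    dice,
    evaluate_image,
    instance_f1,
    iou,
    mask_map,
    pixel_confusion,
    precision,
    recall,
    summarize,
)
from colposeg.model import ColposegError
from conftest import rect_mask


# ---------------------------------------------------------------------------
# pixel confusion and formulas


def test_confusion_identical_masks():
    m = rect_mask(2, 2, 10, 10)
    assert pixel_confusion(m, m) == PixelConfusion(100, 0, 0)


def test_confusion_disjoint_regions():
    a = rect_mask(0, 0, 5, 10)
    b = rect_mask(20, 20, 5, 10)
    assert pixel_confusion(a, b) == PixelConfusion(0, 50, 50)


def test_confusion_half_overlap():
    gt = rect_mask(0, 0, 10, 10)
    pred = rect_mask(0, 0, 10, 5)
    assert pixel_confusion(pred, gt) == PixelConfusion(50, 0, 50)


def test_confusion_size_mismatch_errors():
    with pytest.raises(ColposegError, match="frame"):
        pixel_confusion(BinaryMask.zeros(4, 4), BinaryMask.zeros(5, 5))


def test_hand_computed_metric_values():
    c = PixelConfusion(50, 0, 50)
    assert dice(c) == pytest.approx(2 / 3, abs=1e-9)
    assert iou(c) == pytest.approx(0.5, abs=1e-9)
    assert precision(c) == pytest.approx(1.0, abs=1e-9)
    assert recall(c) == pytest.approx(0.5, abs=1e-9)
    swapped = PixelConfusion(50, 50, 0)  # fp/fn exchange
    assert iou(swapped) == pytest.approx(0.5, abs=1e-9)
    assert precision(swapped) == pytest.approx(0.5, abs=1e-9)
    assert recall(swapped) == pytest.approx(1.0, abs=1e-9)


def test_empty_confusion_scores_zero():
    c = PixelConfusion(0, 0, 0)
    assert dice(c) == 0.0 and iou(c) == 0.0


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    tp=st.integers(0, 10_000),
    fp=st.integers(0, 10_000),
    fn=st.integers(0, 10_000),
)
def test_metric_identities(tp, fp, fn):
    """Dice = 2*IoU/(1+IoU) and Dice = harmonic mean of precision & recall."""
    c = PixelConfusion(tp, fp, fn)
    if tp + fp + fn == 0:
        return
    d, j, p, r = dice(c), iou(c), precision(c), recall(c)
    assert d == pytest.approx(2 * j / (1 + j), abs=1e-9)
    if p + r > 0:
        assert d == pytest.approx(2 * p * r / (p + r), abs=1e-9)
    # monotonicity in tp
    c2 = PixelConfusion(tp + 10, fp, fn)
    assert dice(c2) >= d and iou(c2) >= j
    assert precision(c2) >= p and recall(c2) >= r


def test_translation_invariance():
    gt = rect_mask(5, 5, 8, 12)
    pred = rect_mask(5, 8, 8, 12)
    moved_gt = rect_mask(15, 15, 8, 12)
    moved_pred = rect_mask(15, 18, 8, 12)
    assert dice(pixel_confusion(pred, gt)) == dice(pixel_confusion(moved_pred, moved_gt))


# ---------------------------------------------------------------------------
# evaluate_image


def test_exact_prediction_scores_ones():
    gt = rect_mask(3, 3, 10, 10)
    record = evaluate_image([InstancePrediction(0, "x", gt, 1.0)], [gt], "x")
    for value in (record.dice, record.iou, record.precision, record.recall):
        assert value == pytest.approx(1.0, abs=1e-9)


def test_missing_prediction_scores_zero_recall():
    record = evaluate_image([], [rect_mask(3, 3, 10, 10)], "x")
    assert record.dice == 0.0 and record.recall == 0.0


def test_instance_union_idempotence():
    gt = rect_mask(5, 5, 10, 10)
    p1 = InstancePrediction(0, "x", rect_mask(5, 5, 10, 6), 0.9)
    p2 = InstancePrediction(0, "x", rect_mask(5, 8, 10, 7), 0.8)
    union = BinaryMask(p1.mask.membership | p2.mask.membership)
    split_record = evaluate_image([p1, p2], [gt], "x")
    union_record = evaluate_image([InstancePrediction(0, "x", union, 1.0)], [gt], "x")
    assert split_record == MetricRecord(
        0, "x", union_record.dice, union_record.iou, union_record.precision, union_record.recall
    )


# ---------------------------------------------------------------------------
# summarize


def test_summary_single_record():
    s = summarize([MetricRecord(0, "x", 0.8, 0.7, 0.9, 0.85)])
    assert s.dice.mean == s.dice.median == 0.8
    assert s.dice.sd == 0.0


def test_summary_two_point_spread():
    records = [MetricRecord(0, "x", 0, 0, 0, 0), MetricRecord(1, "x", 1, 1, 1, 1)]
    s = summarize(records)
    assert s.dice.mean == 0.5 and s.dice.median == 0.5


def test_summary_empty_errors():
    with pytest.raises(ColposegError):
        summarize([])


def test_summary_matches_streaming_oracle():
    """Mean/SD from a Welford accumulator, median from a sort — both independent."""
    rng = np.random.default_rng(17)
    values = rng.beta(2.0, 3.0, size=1000)
    records = [MetricRecord(i, "x", float(v), 0.0, 0.0, 0.0) for i, v in enumerate(values)]
    mean_acc, m2, n = 0.0, 0.0, 0
    for v in values:
        n += 1
        delta = v - mean_acc
        mean_acc += delta / n
        m2 += delta * (v - mean_acc)
    sd = (m2 / (n - 1)) ** 0.5
    ordered = sorted(values)
    median = 0.5 * (ordered[499] + ordered[500])
    s = summarize(records)
    assert s.dice.mean == pytest.approx(mean_acc, abs=1e-12)
    assert s.dice.sd == pytest.approx(sd, abs=1e-12)
    assert s.dice.median == pytest.approx(median, abs=1e-12)


def test_summary_row_formatting():
    s = summarize([MetricRecord(0, "x", 1.0, 1.0, 1.0, 1.0)])
    assert s.format_row() == "\t".join(["1.00 (1.00) ± 0.00"] * 4)


# ---------------------------------------------------------------------------
# instance-level matching: brute-force AP oracle


def _brute_force_ap(preds, gts, frame, threshold):
    """Naive AP: re-run greedy matching from scratch for every cutoff and
    scan max-precision-at-recall directly over the 101 recall points."""
    w, h = frame
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, preds[i].image_id, i))
    n_gt = len(gts)
    if n_gt == 0:
        return 0.0
    pr_points = []
    for k in range(1, len(order) + 1):
        matched = [False] * n_gt
        tp = 0
        for i in order[:k]:
            best_j, best_iou = -1, -1.0
            pm = preds[i].binary_mask(w, h).membership
            for j, (img, gm) in enumerate(gts):
                if matched[j] or img != preds[i].image_id:
                    continue
                inter = int((pm & gm.membership).sum())
                union = int((pm | gm.membership).sum())
                value = inter / union if union else 0.0
                if value > best_iou:
                    best_iou, best_j = value, j
            if best_iou >= threshold:
                matched[best_j] = True
                tp += 1
        pr_points.append((tp / n_gt, tp / k))
    ap = 0.0
    for r in RECALL_POINTS:
        candidates = [p for rec, p in pr_points if rec >= r]
        ap += max(candidates) if candidates else 0.0
    return ap / len(RECALL_POINTS)


def _toy_instances(rng):
    """Random toy set: <=3 GT rectangles, <=5 predictions on a 32x32 frame."""
    n_gt = int(rng.integers(0, 4))
    n_pred = int(rng.integers(0, 6))
    gts = []
    for _ in range(n_gt):
        r, c = rng.integers(0, 18, size=2)
        gts.append((0, rect_mask(int(r), int(c), 10, 10, frame=(32, 32))))
    confidences = rng.permutation(np.linspace(0.3, 0.95, n_pred)) if n_pred else []
    preds = []
    for i in range(n_pred):
        if gts and rng.random() < 0.7:  # perturb a GT box
            base = gts[int(rng.integers(0, len(gts)))][1]
            rows, cols = np.nonzero(base.membership)
            dr, dc = rng.integers(-4, 5, size=2)
            r0 = int(np.clip(rows.min() + dr, 0, 22))
            c0 = int(np.clip(cols.min() + dc, 0, 22))
            mask = rect_mask(r0, c0, 10, 10, frame=(32, 32))
        else:
            r, c = rng.integers(0, 18, size=2)
            mask = rect_mask(int(r), int(c), 10, 10, frame=(32, 32))
        preds.append(InstancePrediction(0, "x", mask, float(confidences[i])))
    return preds, gts


def test_mask_map_perfect_predictions():
    gts = [(0, rect_mask(2, 2, 10, 10)), (1, rect_mask(5, 5, 8, 8))]
    preds = [InstancePrediction(i, "x", m, 1.0) for i, m in gts]
    result = mask_map(preds, gts, (40, 40))
    assert result.map50_95 == 1.0 and result.map50 == 1.0


def test_mask_map_no_predictions_is_zero():
    gts = [(0, rect_mask(2, 2, 10, 10))]
    assert mask_map([], gts, (40, 40)).map50_95 == 0.0


def test_mask_map_no_gt_no_preds_is_zero():
    assert mask_map([], [], (40, 40)).map50_95 == 0.0


def test_mask_map_matches_brute_force_oracle():
    rng = np.random.default_rng(23)
    for _ in range(60):
        preds, gts = _toy_instances(rng)
        result = mask_map(preds, gts, (32, 32))
        for t in IOU_THRESHOLDS:
            oracle = _brute_force_ap(preds, gts, (32, 32), float(t))
            assert result.per_threshold[float(t)] == pytest.approx(oracle, abs=1e-12)


def test_map50_95_is_mean_of_thresholds():
    rng = np.random.default_rng(29)
    preds, gts = _toy_instances(rng)
    result = mask_map(preds, gts, (32, 32))
    assert result.map50_95 == pytest.approx(
        np.mean(list(result.per_threshold.values())), abs=1e-12
    )


# ---------------------------------------------------------------------------
# instance F1 and composite objective


def test_instance_f1_perfect():
    gts = [(0, rect_mask(2, 2, 10, 10)), (0, rect_mask(20, 20, 8, 8))]
    preds = [InstancePrediction(0, "x", m, 0.9) for _, m in gts]
    assert instance_f1(preds, gts, (40, 40)) == 1.0


def test_instance_f1_all_below_threshold():
    gts = [(0, rect_mask(0, 0, 8, 8))]
    preds = [InstancePrediction(0, "x", rect_mask(20, 20, 8, 8), 0.9)]
    assert instance_f1(preds, gts, (40, 40)) == 0.0


def test_instance_f1_mixed_counts():
    """2 TP + 1 FP + 1 FN at the optimal cutoff -> F1 = 2/3."""
    gts = [
        (0, rect_mask(0, 0, 10, 10)),
        (0, rect_mask(15, 15, 10, 10)),
        (0, rect_mask(28, 28, 10, 10, frame=(40, 40))),
    ]
    preds = [
        InstancePrediction(0, "x", rect_mask(0, 0, 10, 10), 0.9),
        InstancePrediction(0, "x", rect_mask(0, 20, 5, 5), 0.85),  # FP outranks a TP
        InstancePrediction(0, "x", rect_mask(15, 15, 10, 10), 0.8),
    ]
    assert instance_f1(preds, gts, (40, 40)) == pytest.approx(2 / 3, abs=1e-12)


def test_composite_objective_values():
    assert composite_objective(1.0, 1.0) == 1.0
    assert composite_objective(1.0, 0.0) == 0.7
    assert composite_objective(0.8, 0.5) == pytest.approx(0.71, abs=1e-12)


def test_composite_objective_rejects_out_of_range():
    with pytest.raises(ValueError):
        composite_objective(1.2, 0.0)
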