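"""Detection and yield-ranking evaluation.

Three families of metrics live here:

* detection quality — average precision at a fixed IoU threshold (0.5 by
  default), with all-points precision-recall interpolation, and mAP as the
  mean over classes;
* count agreement — Pearson correlation, mean absolute error, and the
  predicted/true standard-deviation ratio between estimated and hand-counted
  plot pod counts;
* breeding selection — confusion counts and accuracy/sensitivity/specificity
  of advancing the top 20% or 30% of plots by predicted count versus by true
  count ("positive" = selected), with half-up rounding to two decimals as
  breeders report them, plus the pods-to-seeds conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import floor

import numpy as np
from scipy import stats

from .detector import BoundingBox, iou_matrix, boxes_to_array


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------

@dataclass
class DetectionEvalResult:
    ap_per_class: dict[str, float]
    mAP: float
    iou_threshold: float
    pr_points: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (recall, precision)


def _match_detections(detections, truths, iou_threshold):
    """Score-descending greedy matching to the unmatched truth of highest IoU."""
    order = np.argsort(-np.array([d.score for d in detections]), kind="stable")
    darr = boxes_to_array(detections)
    tarr = boxes_to_array(truths)
    m = iou_matrix(darr, tarr)
    used = np.zeros(len(truths), bool)
    tp = np.zeros(len(detections), bool)
    for i in order:
        cand = np.where(~used & (m[i] >= iou_threshold))[0]
        if cand.size:
            best = cand[np.argmax(m[i, cand])]
            used[best] = True
            tp[i] = True
    return tp[order]


def average_precision(detections: list[BoundingBox], truths: list[BoundingBox],
                      iou_threshold: float = 0.5):
    """AP at one IoU threshold with all-points interpolation.

    Returns ``(ap, recall, precision)``; raises if there are no ground-truth
    boxes, where the metric is undefined.
    """
    if len(truths) == 0:
        raise ValueError("average precision is undefined without ground-truth boxes")
    if len(detections) == 0:
        return 0.0, np.array([0.0]), np.array([1.0])
    tp = _match_detections(detections, truths, iou_threshold)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / len(truths)
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope, integrated over recall (all-points interpolation)
    mrec = np.concatenate([[0.0], recall])
    mpre = np.concatenate([[1.0], precision])
    for i in range(mpre.size - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    ap = float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))
    return ap, recall, precision


def evaluate_detections(detections_by_image: dict, truths_by_image: dict,
                        iou_threshold: float = 0.5) -> DetectionEvalResult:
    """Pool detections across images per class and report AP/mAP.

    Detections from different images never match each other's truths; the PR
    curve is built over the pooled, score-sorted detections as in the VOC
    protocol.
    """
    labels = sorted({b.label for bs in truths_by_image.values() for b in bs})
    if not labels:
        raise ValueError("no ground-truth boxes in any image")
    ap_per_class, pr = {}, {}
    for label in labels:
        rows = []  # (score, is_tp) pooled
        n_truth = 0
        for img, truths in truths_by_image.items():
            t = [b for b in truths if b.label == label]
            d = [b for b in detections_by_image.get(img, []) if b.label == label]
            n_truth += len(t)
            if d and t:
                order = np.argsort(-np.array([b.score for b in d]), kind="stable")
                tp = _match_detections(d, t, iou_threshold)
                scores = np.array([d[i].score for i in order])
                rows.extend(zip(scores, tp))
            elif d:
                rows.extend((b.score, False) for b in sorted(d, key=lambda b: -b.score))
        if n_truth == 0:
            continue
        if not rows:
            ap_per_class[label] = 0.0
            pr[label] = (np.array([0.0]), np.array([1.0]))
            continue
        rows.sort(key=lambda r: -r[0])
        tp = np.array([r[1] for r in rows], bool)
        cum_tp, cum_fp = np.cumsum(tp), np.cumsum(~tp)
        recall = cum_tp / n_truth
        precision = cum_tp / (cum_tp + cum_fp)
        mrec = np.concatenate([[0.0], recall])
        mpre = np.concatenate([[1.0], precision])
        for i in range(mpre.size - 2, -1, -1):
            mpre[i] = max(mpre[i], mpre[i + 1])
        ap_per_class[label] = float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))
        pr[label] = (recall, precision)
    mAP = float(np.mean(list(ap_per_class.values())))
    return DetectionEvalResult(ap_per_class, mAP, iou_threshold, pr)


# ---------------------------------------------------------------------------
# Count agreement
# ---------------------------------------------------------------------------

@dataclass
class CountAgreement:
    pearson_r: float
    mae: float
    std_ratio: float   # predicted std / true std
    n: int


def count_agreement(predicted, truth) -> CountAgreement:
    p = np.asarray(predicted, float)
    t = np.asarray(truth, float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 3:
        raise ValueError("need paired 1-d vectors with n >= 3")
    if not (np.isfinite(p).all() and np.isfinite(t).all()):
        raise ValueError("non-finite counts")
    if np.std(p) == 0 or np.std(t) == 0:
        raise ValueError("correlation undefined for zero-variance counts")
    r = float(stats.pearsonr(p, t).statistic)
    return CountAgreement(r, float(np.mean(np.abs(p - t))),
                          float(np.std(p) / np.std(t)), p.size)


# ---------------------------------------------------------------------------
# Selection ranking
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _round2(num: int, den: int) -> float:
    """Exact half-up rounding of num/den to 2 decimals (0.925 -> 0.93)."""
    return float((Decimal(num) / Decimal(den)).quantize(Decimal("0.01"),
                                                        rounding=ROUND_HALF_UP))


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    return {
        "accuracy": _round2(c.tp + c.tn, c.total),
        "sensitivity": _round2(c.tp, c.tp + c.fn),
        "specificity": _round2(c.tn, c.tn + c.fp),
    }


def round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def select_top_fraction(values, fraction: float | None = None,
                        k_override: int | None = None) -> set[int]:
    """Indices of the top-k values; ties at the cutoff are all included.

    ``k`` is the explicit override when given, else ``round-half-up(n *
    fraction)``. Because cutoff ties are included wholesale, the selected set
    may exceed the nominal k; callers see the actual size.
    """
    v = np.asarray(values, float)
    n = v.size
    if k_override is not None:
        k = int(k_override)
    else:
        if fraction is None or not 0.0 < fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1) unless k_override is given")
        k = round_half_up(n * fraction)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k <= 0:
        return set()
    cutoff = np.sort(v)[::-1][k - 1]
    return set(np.where(v >= cutoff)[0].tolist())


@dataclass
class RankingReport:
    selection_fraction: float | None
    k_selected: int
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float


def report_from_confusion(counts: ConfusionCounts,
                          fraction: float | None = None) -> RankingReport:
    """Metrics straight from given confusion counts (half-up, 2 decimals)."""
    m = metrics_from_confusion(counts)
    return RankingReport(fraction, counts.tp + counts.fn, counts,
                         m["accuracy"], m["sensitivity"], m["specificity"])


def ranking_report(predicted_counts, true_counts, fraction: float | None = None,
                   k_truth: int | None = None, k_pred: int | None = None) -> RankingReport:
    """Selection confusion of predicted vs true top-k plots.

    Truth-positives are the top-k plots by true count, predicted-positives
    the top-k by predicted count; a plot is a true positive when it sits in
    both sets. ``k_truth``/``k_pred`` override the fraction-derived k
    separately (printed tables sometimes imply unequal effective k through
    ground-truth ties).
    """
    p = np.asarray(predicted_counts, float)
    t = np.asarray(true_counts, float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predicted and true counts must be paired 1-d vectors")
    truth_sel = select_top_fraction(t, fraction, k_truth)
    pred_sel = select_top_fraction(p, fraction, k_pred)
    n = p.size
    tp = len(truth_sel & pred_sel)
    fp = len(pred_sel - truth_sel)
    fn = len(truth_sel - pred_sel)
    counts = ConfusionCounts(tp, n - tp - fp - fn, fp, fn)
    rep = report_from_confusion(counts, fraction)
    rep.k_selected = len(truth_sel)
    return rep


# ---------------------------------------------------------------------------
# Yield conversion
# ---------------------------------------------------------------------------

def pods_to_seeds(pod_count: float, seeds_per_pod: float) -> float:
    """Seed-count estimate from a pod count and a seeds-per-pod multiplier.

    Field multipliers of about 2.0 (in-field) to 2.2 (controlled imaging)
    are typical for mature soybean.
    """
    if pod_count < 0 or seeds_per_pod < 0:
        raise ValueError("pod count and seeds-per-pod must be non-negative")
    return float(pod_count) * float(seeds_per_pod)
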