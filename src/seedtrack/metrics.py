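"""Detection and tracking evaluation statistics.

Static detection quality: precision P = TP/(TP+FP), recall R = TP/(TP+FN),
average precision AP as the area under the precision-recall curve, and mAP
as the class mean. Tracking quality: miss rate Mm = FN/(FN+TP), false rate
Mf = FP/(FP+TN) with TN read as the other class's correct detections,
CLEAR-MOT accuracy MOTA = 1 - sum(misses + false positives + identity
switches)/sum(ground-truth count), and the field-protocol detection
accuracy Dt = R_model / R_truth (ratio of the estimated to the manually
counted missed transplanting rate).

Percentages are returned on the 0-100 scale; AP and MOTA are fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import BoundingBox, iou, iou_matrix
from .tracking import hungarian_assign

__all__ = [
    "ConfusionCounts",
    "TrackingEvents",
    "PRCurve",
    "precision",
    "recall",
    "miss_rate",
    "false_rate",
    "match_detections",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "mota",
    "tracking_events_from_gt",
    "detection_accuracy",
]


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies. TN means correctly detected objects of the
    *other* class; it feeds only the false-detection rate Mf."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class TrackingEvents:
    """Per-frame CLEAR-MOT event tallies."""

    misses: list[int] = field(default_factory=list)  # NM_m per frame
    false_positives: list[int] = field(default_factory=list)  # NM_f per frame
    id_switches: list[int] = field(default_factory=list)  # IDS per frame
    gt_counts: list[int] = field(default_factory=list)  # GT_t per frame


@dataclass
class PRCurve:
    """(recall, precision) pairs ordered along the confidence sweep."""

    points: list[tuple[float, float]] = field(default_factory=list)


def _pct(num: float, den: float, what: str) -> float:
    if den <= 0:
        raise ZeroDivisionError(f"{what} is undefined: denominator is zero")
    return 100.0 * num / den


def precision(c: ConfusionCounts) -> float:
    """P = TP/(TP+FP) x 100%."""
    return _pct(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    """R = TP/(TP+FN) x 100%."""
    return _pct(c.tp, c.tp + c.fn, "recall")


def miss_rate(c: ConfusionCounts) -> float:
    """Mm = FN/(FN+TP) x 100%; equals 100 - recall."""
    return _pct(c.fn, c.fn + c.tp, "miss rate")


def false_rate(c: ConfusionCounts) -> float:
    """Mf = FP/(FP+TN) x 100%."""
    return _pct(c.fp, c.fp + c.tn, "false rate")


def match_detections(
    detections: list[tuple[BoundingBox, float]],
    ground_truths: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[ConfusionCounts, list[bool]]:
    """Greedy confidence-ordered one-to-one matching for one image, one class.

    Detections are visited in descending confidence (ties broken by input
    order, then smaller area) and each claims the unmatched ground truth of
    highest IoU at or above the threshold. Returns the counts and a
    per-detection TP flag in the *input* order.
    """
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i][1], i, detections[i][0].area),
    )
    matched_gt: set[int] = set()
    is_tp = [False] * len(detections)
    for i in order:
        box = detections[i][0]
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(ground_truths):
            if j in matched_gt:
                continue
            o = iou(box, gt)
            if o >= best_iou and o > 0:
                if o > best_iou or best_j < 0:
                    best_j, best_iou = j, o
        if best_j >= 0:
            matched_gt.add(best_j)
            is_tp[i] = True
    tp = sum(is_tp)
    return (
        ConfusionCounts(tp=tp, fp=len(detections) - tp, fn=len(ground_truths) - len(matched_gt)),
        is_tp,
    )


def pr_curve(
    detections: list[tuple[float, bool]], n_positives: int
) -> PRCurve:
    """Precision-recall curve from (confidence, is_tp) pairs.

    Detections are pooled across images, sorted by descending confidence,
    and cumulated; recall is against ``n_positives`` ground-truth objects.
    """
    if n_positives <= 0 or not detections:
        return PRCurve([])
    order = sorted(range(len(detections)), key=lambda i: (-detections[i][0], i))
    pts: list[tuple[float, float]] = []
    tp = fp = 0
    for i in order:
        if detections[i][1]:
            tp += 1
        else:
            fp += 1
        pts.append((tp / n_positives, tp / (tp + fp)))
    return PRCurve(pts)


def average_precision(curve: PRCurve, mode: str = "allpoint") -> float:
    """Area under the precision envelope of a PR curve, as a fraction.

    ``allpoint`` (default) integrates the monotone non-increasing precision
    envelope over recall; ``11point`` averages the envelope sampled at
    recalls 0, 0.1, ..., 1.0.
    """
    if not curve.points:
        return 0.0
    rec = np.array([p[0] for p in curve.points])
    prec = np.array([p[1] for p in curve.points])
    order = np.argsort(rec, kind="stable")
    rec, prec = rec[order], prec[order]
    # monotone envelope: precision at recall r is the max precision at any
    # recall >= r
    env = np.maximum.accumulate(prec[::-1])[::-1]
    if mode == "allpoint":
        r_prev = 0.0
        area = 0.0
        for r, p in zip(rec, env):
            area += (r - r_prev) * p
            r_prev = r
        return float(area)
    if mode == "11point":
        samples = []
        for r in np.linspace(0.0, 1.0, 11):
            mask = rec >= r - 1e-12
            samples.append(float(env[mask][0]) if mask.any() else 0.0)
        return float(np.mean(samples))
    raise ValueError(f"unknown AP mode {mode!r}")


def mean_ap(aps: list[float]) -> float:
    """mAP = mean of the per-class APs, in percent."""
    if not aps:
        raise ValueError("mean_ap of an empty list is undefined")
    return 100.0 * float(np.mean(aps))


def mota(events: TrackingEvents) -> float:
    """MOTA = 1 - sum(NM_m + NM_f + IDS) / sum(GT_t); can be negative."""
    gt_total = sum(events.gt_counts)
    if gt_total <= 0:
        raise ZeroDivisionError("MOTA undefined: no ground-truth objects")
    errors = sum(events.misses) + sum(events.false_positives) + sum(events.id_switches)
    return 1.0 - errors / gt_total


def tracking_events_from_gt(
    hypotheses: dict[int, list[tuple[int, BoundingBox]]],
    ground_truth: dict[int, list[tuple[int, BoundingBox]]],
    iou_threshold: float = 0.5,
) -> TrackingEvents:
    """CLEAR-MOT event extraction from frame-aligned (id, box) streams.

    Both arguments map frame index -> list of (track_id, box). Per frame,
    hypotheses are matched to truths by Hungarian assignment on 1 - IoU
    with overlaps below the threshold infeasible; unmatched truths are
    misses, unmatched hypotheses false positives, and a truth matched to a
    different hypothesis id than its previous match is an identity switch.
    """
    events = TrackingEvents()
    last_hyp_for_gt: dict[int, int] = {}
    for frame in sorted(set(hypotheses) | set(ground_truth)):
        gts = ground_truth.get(frame, [])
        hyps = hypotheses.get(frame, [])
        events.gt_counts.append(len(gts))
        if gts and hyps:
            overlaps = iou_matrix([b for _, b in gts], [b for _, b in hyps])
            cost = 1.0 - overlaps
            infeasible = overlaps < iou_threshold
            pairs = hungarian_assign(cost, infeasible)
        else:
            pairs = []
        switches = 0
        for gi, hi in pairs:
            gt_id, hyp_id = gts[gi][0], hyps[hi][0]
            prev = last_hyp_for_gt.get(gt_id)
            if prev is not None and prev != hyp_id:
                switches += 1
            last_hyp_for_gt[gt_id] = hyp_id
        events.misses.append(len(gts) - len(pairs))
        events.false_positives.append(len(hyps) - len(pairs))
        events.id_switches.append(switches)
    return events


def detection_accuracy(r_model: float, r_truth: float) -> tuple[float, bool]:
    """Dt = R_model / R_truth x 100%.

    Returns the literal ratio (which can exceed 100 when the model
    overestimates) together with an overestimate flag.
    """
    if r_truth <= 0:
        raise ZeroDivisionError("Dt undefined: truth rate is zero")
    dt = 100.0 * r_model / r_truth
    return dt, dt > 100.0
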