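"""Object-detection quality metrics: IoU, greedy matching, precision/recall,
and interpolated average precision (AP).

The protocol follows standard Pascal-VOC practice. Per frame and per class,
detections are matched greedily in descending-confidence order to the
unmatched ground-truth box of highest IoU; a match with IoU at or above the
threshold is a true positive, anything else a false positive, and ground
truths left unmatched are false negatives. Pooled TP/FP flags, ranked by
confidence over the whole dataset, yield the precision-recall curve; AP is
the area under its monotone (max-precision-at-each-recall) envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxio import Box, DetectionRecord, FrameRecord, filter_confidence

__all__ = ["MatchResult", "EvalReport", "iou", "match_frame", "average_precision", "evaluate"]


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes: |a ∩ b| / |a ∪ b|, in [0, 1].

    Symmetric; 0 for disjoint boxes, 1 iff the boxes coincide.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    """Outcome of matching one frame's detections against its ground truth."""

    tp_count: int
    fp_count: int
    fn_count: int
    matched_pairs: list[tuple[int, int, float]]  # (gt index, det index, IoU)
    ranked_flags: list[tuple[float, bool]]       # (confidence, is_tp), conf-desc


def match_frame(
    ground_truth: Sequence[Box],
    detections: Sequence[DetectionRecord],
    iou_threshold: float,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth boxes.

    Detections are processed in descending confidence (ties keep input
    order); each claims the unmatched ground truth of highest IoU and is a
    true positive iff that IoU >= ``iou_threshold``. Each ground truth can be
    claimed at most once; later detections on an already-claimed ground truth
    are false positives.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1]")

    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    claimed = [False] * len(ground_truth)
    pairs: list[tuple[int, int, float]] = []
    flags: list[tuple[float, bool]] = []
    for di in order:
        det = detections[di]
        best_iou, best_gi = 0.0, -1
        for gi, gt in enumerate(ground_truth):
            if claimed[gi]:
                continue
            v = iou(gt, det.box)
            if v > best_iou:
                best_iou, best_gi = v, gi
        is_tp = best_gi >= 0 and best_iou >= iou_threshold
        if is_tp:
            claimed[best_gi] = True
            pairs.append((best_gi, di, best_iou))
        flags.append((det.confidence, is_tp))

    tp = len(pairs)
    return MatchResult(
        tp_count=tp,
        fp_count=len(detections) - tp,
        fn_count=len(ground_truth) - tp,
        matched_pairs=pairs,
        ranked_flags=flags,
    )


def average_precision(
    ranked_flags: Sequence[tuple[float, bool]], total_ground_truth: int
) -> tuple[float, list[tuple[float, float]]]:
    """Interpolated AP from confidence-ranked TP/FP flags.

    The cumulative precision-recall curve is built along the ranking, each
    precision is replaced by the maximum precision at any recall >= its own
    (the monotone envelope), and AP is the sum of recall increments times the
    interpolated precision. Returns ``(ap, pr_points)`` where ``pr_points``
    is the raw (recall, precision) sequence along the ranking.
    """
    if total_ground_truth < 1:
        raise ValueError("average precision undefined with zero ground truths")
    if not ranked_flags:
        return 0.0, []

    flags = sorted(ranked_flags, key=lambda cf: -cf[0])
    tps = np.cumsum([1 if f else 0 for _, f in flags])
    ranks = np.arange(1, len(flags) + 1)
    precision = tps / ranks
    recall = tps / total_ground_truth

    # monotone envelope: max precision at any recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        if r > prev_recall:
            ap += (r - prev_recall) * p
            prev_recall = r
    return float(ap), list(zip(recall.tolist(), precision.tolist()))


@dataclass
class EvalReport:
    """Per-class detection quality summary."""

    label: str
    confidence_threshold: float
    iou_threshold: float
    precision: float
    recall: float
    average_precision: float
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    tp_count: int = 0
    fp_count: int = 0
    fn_count: int = 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "confidence_threshold": self.confidence_threshold,
            "iou_threshold": self.iou_threshold,
            "precision": self.precision,
            "recall": self.recall,
            "average_precision": self.average_precision,
            "tp_count": self.tp_count,
            "fp_count": self.fp_count,
            "fn_count": self.fn_count,
            "pr_points": [list(p) for p in self.pr_points],
        }


def evaluate(
    frames: Sequence[FrameRecord],
    label: str,
    confidence_threshold: float,
    iou_threshold: float,
) -> EvalReport:
    """Characterize a detector on annotated frames for one class.

    Applies the confidence filter, matches every frame, pools the ranked
    TP/FP flags over the dataset and reports precision = TP/(TP+FP),
    recall (sensitivity) = TP/(TP+FN), and interpolated AP.
    """
    filtered = filter_confidence(frames, label, confidence_threshold)
    total_gt = sum(1 for fr in filtered for _, lbl in fr.ground_truth if lbl == label)
    if total_gt == 0:
        raise ValueError(f"no ground-truth annotations for label {label!r}")

    pooled: list[tuple[float, bool]] = []
    tp = fp = fn = 0
    for fr in filtered:
        gts = [box for box, lbl in fr.ground_truth if lbl == label]
        dets = [d for d in fr.detections if d.label == label]
        res = match_frame(gts, dets, iou_threshold)
        pooled.extend(res.ranked_flags)
        tp += res.tp_count
        fp += res.fp_count
        fn += res.fn_count

    ap, pr_points = average_precision(pooled, total_gt)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    return EvalReport(
        label=label,
        confidence_threshold=confidence_threshold,
        iou_threshold=iou_threshold,
        precision=precision,
        recall=recall,
        average_precision=ap,
        pr_points=pr_points,
        tp_count=tp,
        fp_count=fp,
        fn_count=fn,
    )
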