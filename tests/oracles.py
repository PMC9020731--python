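"""Independent brute-force reference implementations used only to check the
library. Deliberately naive: double loops, exhaustive enumeration, no shared
code with the package internals beyond the Box container."""

from __future__ import annotations

from wormbox.boxio import Box, FrameRecord


def iou_brute(a: Box, b: Box) -> float:
    """IoU recomputed independently of the package, by interval
    arithmetic per axis."""
    def overlap(lo1, hi1, lo2, hi2):
        return max(0.0, min(hi1, hi2) - max(lo1, lo2))

    inter = overlap(a.x_min, a.x_max, b.x_min, b.x_max) * overlap(
        a.y_min, a.y_max, b.y_min, b.y_max
    )
    union = (
        (a.x_max - a.x_min) * (a.y_max - a.y_min)
        + (b.x_max - b.x_min) * (b.y_max - b.y_min)
        - inter
    )
    return inter / union


def pr_ap_brute(
    frames: list[FrameRecord], label: str, conf_thr: float, iou_thr: float
) -> tuple[float, float, float]:
    """(precision, recall, AP) recomputed from scratch.

    Re-implements greedy per-frame matching with explicit loops, then builds
    the full PR curve point by point and integrates the max-precision
    envelope by direct enumeration over every recall step.
    """
    flags: list[tuple[float, bool]] = []
    total_gt = 0
    tp_total = fp_total = 0
    for fr in frames:
        gts = [b for b, l in fr.ground_truth if l == label]
        dets = [d for d in fr.detections if d.label == label and d.confidence >= conf_thr]
        total_gt += len(gts)
        used = set()
        for d in sorted(dets, key=lambda d: -d.confidence):
            best, best_i = 0.0, None
            for i, g in enumerate(gts):
                if i in used:
                    continue
                v = iou_brute(g, d.box)
                if v > best:
                    best, best_i = v, i
            if best_i is not None and best >= iou_thr:
                used.add(best_i)
                flags.append((d.confidence, True))
                tp_total += 1
            else:
                flags.append((d.confidence, False))
                fp_total += 1

    flags.sort(key=lambda cf: -cf[0])
    recalls, precisions = [], []
    tp = 0
    for k, (_, is_tp) in enumerate(flags, start=1):
        tp += is_tp
        precisions.append(tp / k)
        recalls.append(tp / total_gt)

    ap = 0.0
    prev_r = 0.0
    for i, r in enumerate(recalls):
        if r > prev_r:
            p_interp = max(precisions[j] for j in range(len(recalls)) if recalls[j] >= r)
            ap += (r - prev_r) * p_interp
            prev_r = r

    precision = tp_total / (tp_total + fp_total) if tp_total + fp_total else 0.0
    recall = tp_total / total_gt if total_gt else 0.0
    return precision, recall, ap


def ks_d_brute(a, b) -> float:
    """KS D by evaluating both ECDFs at every observed point, double loop."""
    a = list(map(float, a))
    b = list(map(float, b))
    d = 0.0
    for x in a + b:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def solve_iou_shift(width: float, target_iou: float) -> float:
    """Horizontal shift giving a target IoU for two equal boxes, by bisection
    on the overlap equation (independent of the constructive formula)."""
    lo, hi = 0.0, width
    for _ in range(200):
        mid = (lo + hi) / 2
        iou = (width - mid) / (width + mid)
        if iou > target_iou:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
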