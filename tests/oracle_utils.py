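"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately slow and literal — dense convolutions,
per-pixel scalar loops, repeated full-list scans — so that it shares no
code path with the vectorized package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

from panofrac.annotations import BoundingBox


def dense_gaussian(field: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian blur by explicit dense convolution.

    Sampled kernel truncated at radius int(3*sigma + 0.5), normalized to
    unit sum, with symmetric (reflect) padding.
    """
    r = int(3.0 * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    k2 = np.outer(k1, k1)
    padded = np.pad(field, r, mode="symmetric")
    h, w = field.shape
    out = np.empty_like(field, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = float((padded[i : i + 2 * r + 1, j : j + 2 * r + 1] * k2).sum())
    return out


def slat_loop(ln: np.ndarray, sigma: float, rcs: float = 255.0) -> np.ndarray:
    """Straight-line scalar reimplementation of the single-scale transform.

    Per pixel: adaptation luminance from the dense Gaussian oracle, then
    Lmin = 0.0212 + 0.0185*Lan^1.0314, Lmax = 25.83 + 30.82*Lan^0.6753,
    gamma = 0.444 + 0.045*ln(Lan + 0.6034),
    f = |(Ln - Lmin)/(Lmax - Lmin)|^gamma, then the global gain/offset
    f -> rcs*(f - fmin)/(fmax - fmin).
    """
    lan = dense_gaussian(ln, sigma)
    h, w = ln.shape
    f = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            a = lan[i, j]
            lmin = 0.0212 + 0.0185 * a**1.0314
            lmax = 25.83 + 30.82 * a**0.6753
            g = 0.444 + 0.045 * math.log(a + 0.6034)
            f[i, j] = abs((ln[i, j] - lmin) / (lmax - lmin)) ** g
    fmin, fmax = f.min(), f.max()
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = rcs * f[i, j] / (fmax - fmin) - rcs * fmin / (fmax - fmin)
    return np.clip(out, 0.0, rcs)


def iou_ref(a: BoundingBox, b: BoundingBox) -> float:
    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0


def nms_ref(detections, threshold):
    """Greedy NMS that re-scans the full remaining list every round."""
    remaining = list(detections)
    kept = []
    while remaining:
        best = max(remaining, key=lambda d: d.confidence)
        kept.append(best)
        remaining = [
            d
            for d in remaining
            if d is not best
            and not (
                d.class_id == best.class_id and iou_ref(best.box, d.box) > threshold
            )
        ]
    return kept


def match_ref(preds, truths, thr=0.5, fracture_level=True):
    """Reference matcher: walk predictions in confidence order, scan all truths.

    Returns (tp, fp, fn, pairs) where pairs is a set of (pred, truth) indices.
    """
    remaining_preds = sorted(
        range(len(preds)), key=lambda i: -preds[i].confidence
    )
    taken: dict[int, int] = {}  # truth index -> pred index
    fp = 0
    for pi in remaining_preds:
        candidates = []
        overlaps_taken = False
        for tj in range(len(truths)):
            if truths[tj].class_id != preds[pi].class_id:
                continue
            ov = iou_ref(preds[pi].box, truths[tj].box)
            if ov >= thr:
                if tj in taken:
                    overlaps_taken = True
                else:
                    candidates.append((ov, tj))
        if candidates:
            _, tj = max(candidates)
            taken[tj] = pi
        elif overlaps_taken and fracture_level:
            pass
        else:
            fp += 1
    tp = len(taken)
    fn = len(truths) - tp
    pairs = {(pi, tj) for tj, pi in taken.items()}
    return tp, fp, fn, pairs
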