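"""Detection scoring: IOU matching, precision/recall/F1, per-region reports.

A prediction counts as a true positive when it matches an unmatched
ground-truth fracture of its class with IOU at or above the threshold
(default 0.5). Matching is greedy in descending confidence. In
fracture-level mode (default) extra predictions landing on an
already-matched fracture are ignored rather than counted as false
positives, because scoring is per fracture, not per box, and a
"misdetection" means hitting something that is not a fracture at all.
Accuracy is deliberately not reported: true negatives are undefined when
any region of the mandible could contain a fracture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotations import Annotation, BoundingBox, ClassScheme

__all__ = [
    "MatchResult",
    "MetricReport",
    "iou",
    "match_detections",
    "prf1",
    "region_report",
]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return min(inter / (a.area + b.area - inter), 1.0)


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    #: (prediction index, truth index, iou) per matched pair
    matched_pairs: tuple[tuple[int, int, float], ...]
    #: prediction indices counted as false positives
    fp_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.tp != len(self.matched_pairs):
            raise ValueError("tp must equal the number of matched pairs")
        if self.fp_indices and self.fp != len(self.fp_indices):
            raise ValueError("fp must equal the number of fp indices")


def match_detections(
    preds: Sequence,
    truths: Sequence[Annotation],
    iou_threshold: float = 0.5,
    fracture_level: bool = True,
    class_agnostic: bool = False,
) -> MatchResult:
    """Greedily match predictions to ground-truth fractures.

    Parameters
    ----------
    preds
        Objects with ``box``, ``class_id`` and ``confidence`` attributes.
    truths
        Ground-truth annotations.
    iou_threshold
        Minimum overlap for a match.
    fracture_level
        Ignore duplicate hits on an already-matched truth (neither TP nor
        FP). When off, duplicates count as FP (box-level scoring).
    class_agnostic
        Score localization only: a prediction may match a truth of any class.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError(f"iou threshold {iou_threshold} outside [0, 1]")
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    fp_indices: list[int] = []
    for pi in order:
        pred = preds[pi]
        best_j, best_iou = -1, 0.0
        dup_hit = False
        for tj, truth in enumerate(truths):
            if not class_agnostic and truth.class_id != pred.class_id:
                continue
            ov = iou(pred.box, truth.box)
            if ov < iou_threshold - 1e-12:  # tolerate float noise at thr=1
                continue
            if tj in matched_truth:
                dup_hit = True
                continue
            if ov > best_iou:
                best_j, best_iou = tj, ov
        if best_j >= 0:
            matched_truth.add(best_j)
            pairs.append((pi, best_j, best_iou))
        elif dup_hit and fracture_level:
            pass  # duplicate hit on a fracture already found: not an error
        else:
            fp_indices.append(pi)
    fn = len(truths) - len(matched_truth)
    return MatchResult(
        len(pairs), len(fp_indices), fn, tuple(pairs), tuple(sorted(fp_indices))
    )


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 with a defined-zero convention.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    any ratio with a zero denominator is 0, and F1 is 0 whenever TP is 0.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


@dataclass(frozen=True)
class MetricReport:
    """Global and per-label scores plus diagnosed/undiagnosed fracture counts."""

    precision: float
    recall: float
    f1: float
    per_class: Mapping[str, tuple[float, float, float]]
    diagnosed: Mapping[str, int]
    undiagnosed: Mapping[str, int]

    def to_table(self) -> str:
        rows = [f"{'label':<16}{'precision':>10}{'recall':>10}{'f1':>10}"
                f"{'diagnosed':>11}{'undiagnosed':>13}"]
        for label, (p, r, f) in self.per_class.items():
            rows.append(
                f"{label:<16}{p:>10.3f}{r:>10.3f}{f:>10.3f}"
                f"{self.diagnosed[label]:>11d}{self.undiagnosed[label]:>13d}"
            )
        rows.append(
            f"{'overall':<16}{self.precision:>10.3f}{self.recall:>10.3f}"
            f"{self.f1:>10.3f}{sum(self.diagnosed.values()):>11d}"
            f"{sum(self.undiagnosed.values()):>13d}"
        )
        return "\n".join(rows)


def region_report(
    match: MatchResult,
    preds: Sequence,
    truths: Sequence[Annotation],
    scheme: ClassScheme,
) -> MetricReport:
    """Break the global match down per class label.

    Diagnosed = ground-truth fractures matched by some prediction;
    undiagnosed = never matched. Per-label TP/FN always sum to the global
    counts; unmatched predictions contribute per-label FP.
    """
    for t in truths:
        if not 0 <= t.class_id < len(scheme):
            raise ValueError(
                f"truth class {t.class_id} outside scheme {scheme.name!r}"
            )
    labels = scheme.labels
    tp = dict.fromkeys(labels, 0)
    fp = dict.fromkeys(labels, 0)
    fn = dict.fromkeys(labels, 0)

    matched_preds = {pi for pi, _, _ in match.matched_pairs}
    matched_truths = {tj for _, tj, _ in match.matched_pairs}
    for _, tj, _ in match.matched_pairs:
        tp[labels[truths[tj].class_id]] += 1
    for tj, t in enumerate(truths):
        if tj not in matched_truths:
            fn[labels[t.class_id]] += 1
    # attribute FPs per predicted class; ignored duplicate hits
    # (fracture-level mode) are in neither set
    fp_set = set(match.fp_indices) if match.fp_indices else {
        pi for pi in range(len(preds)) if pi not in matched_preds
    }
    for pi in fp_set:
        cid = preds[pi].class_id
        if 0 <= cid < len(labels):
            fp[labels[cid]] += 1

    per_class = {lab: prf1(tp[lab], fp[lab], fn[lab]) for lab in labels}
    p, r, f = prf1(match.tp, match.fp, match.fn)
    return MetricReport(
        precision=p,
        recall=r,
        f1=f,
        per_class=per_class,
        diagnosed=tp,
        undiagnosed=fn,
    )
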