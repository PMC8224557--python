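"""Detector-head arithmetic and post-processing.

The detector predicts on an S x S grid with B anchor boxes per cell; each
cell encodes B x (5 + C) channels (4 box offsets + 1 objectness + C class
probabilities per anchor). Confidence composition follows the two-stage
YOLO scoring: an objectness-times-IOU confidence, multiplied by the
conditional class probability for the class-specific score.

Post-processing is greedy class-wise NMS, plus a merge step that maps the
predictions of the SLAT- and MLAT-enhanced inference passes back onto the
original radiograph geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotations import BoundingBox
from .evaluation import iou

__all__ = [
    "Detection",
    "GridSpec",
    "PixelBox",
    "feature_map_shape",
    "grid_sizes",
    "confidence_score",
    "class_confidence",
    "greedy_nms",
    "merge_module_predictions",
]


@dataclass(frozen=True)
class Detection:
    """A decoded candidate box in normalized coordinates."""

    box: BoundingBox
    class_id: int
    confidence: float
    module_tag: str = "other"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class GridSpec:
    """One prediction scale: cells per side, anchors per cell, classes, stride."""

    s: int
    b: int
    c: int
    stride: int = 32

    def __post_init__(self) -> None:
        if self.s < 1 or self.b < 1 or self.c < 0 or self.stride < 1:
            raise ValueError(f"invalid grid spec {self}")

    @property
    def input_side(self) -> int:
        return self.s * self.stride


def feature_map_shape(spec: GridSpec) -> tuple[int, int, int]:
    """Tensor shape (S, S, B*(5+C)) of one prediction feature map."""
    return (spec.s, spec.s, spec.b * (5 + spec.c))


def grid_sizes(input_side: int, strides: Sequence[int]) -> list[int]:
    """Cells per side at each prediction stride (608 -> [19, 38, 76])."""
    sizes = []
    for stride in strides:
        if stride < 1 or input_side % stride:
            raise ValueError(f"input side {input_side} not divisible by {stride}")
        sizes.append(input_side // stride)
    return sizes


def _check_unit(name: str, v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name}={v} outside [0, 1]")
    return v


def confidence_score(p_fracture: float, iou_pred_truth: float) -> float:
    """Objectness confidence: Pr(fracture) times box-fit IOU."""
    return _check_unit("p_fracture", p_fracture) * _check_unit(
        "iou", iou_pred_truth
    )


def class_confidence(p_class_given_fracture: float, confidence: float) -> float:
    """Class-specific score: Pr(class | fracture) times the confidence,
    which equals Pr(class) times IOU."""
    return _check_unit("p_class", p_class_given_fracture) * _check_unit(
        "confidence", confidence
    )


def greedy_nms(
    detections: Sequence[Detection], iou_threshold: float = 0.45
) -> list[Detection]:
    """Class-wise greedy non-maximum suppression.

    Per class, repeatedly keep the highest-confidence box and drop every
    same-class box overlapping it above the threshold. Boxes of different
    classes never suppress each other. Kept boxes come out in descending
    confidence; confidence ties break by input order (stable sort).
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError(f"iou threshold {iou_threshold} outside [0, 1]")
    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    kept: list[Detection] = []
    for i in order:
        d = detections[i]
        if all(
            k.class_id != d.class_id or iou(k.box, d.box) <= iou_threshold
            for k in kept
        ):
            kept.append(d)
    return kept


@dataclass(frozen=True)
class PixelBox:
    """Center-based box in pixel units of some image geometry."""

    cx: float
    cy: float
    w: float
    h: float

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )


@dataclass(frozen=True)
class MergedDetection:
    """A detection mapped back to original-radiograph pixel coordinates."""

    box: PixelBox
    class_id: int
    confidence: float
    module_tag: str


def net_to_original(
    box: BoundingBox,
    original_size: tuple[int, int],
    net_side: int = 608,
    letterbox: bool = False,
) -> PixelBox:
    """Map a network-normalized box to original pixel geometry.

    Default inference resize is a uniform (anisotropic) stretch to
    ``net_side`` square, so normalized coordinates carry over directly.
    With ``letterbox`` the aspect ratio was preserved and gray bars padded;
    the padding is undone here.
    """
    ow, oh = original_size
    if ow < 1 or oh < 1:
        raise ValueError(f"invalid original size {original_size}")
    if not letterbox:
        return PixelBox(box.cx * ow, box.cy * oh, box.w * ow, box.h * oh)
    scale = net_side / max(ow, oh)
    pad_x = (net_side - ow * scale) / 2
    pad_y = (net_side - oh * scale) / 2
    return PixelBox(
        (box.cx * net_side - pad_x) / scale,
        (box.cy * net_side - pad_y) / scale,
        box.w * net_side / scale,
        box.h * net_side / scale,
    )


def original_to_net(
    box: PixelBox,
    original_size: tuple[int, int],
    net_side: int = 608,
    letterbox: bool = False,
) -> BoundingBox:
    """Inverse of :func:`net_to_original`."""
    ow, oh = original_size
    if ow < 1 or oh < 1:
        raise ValueError(f"invalid original size {original_size}")
    if not letterbox:
        return BoundingBox(box.cx / ow, box.cy / oh, box.w / ow, box.h / oh)
    scale = net_side / max(ow, oh)
    pad_x = (net_side - ow * scale) / 2
    pad_y = (net_side - oh * scale) / 2
    return BoundingBox(
        (box.cx * scale + pad_x) / net_side,
        (box.cy * scale + pad_y) / net_side,
        box.w * scale / net_side,
        box.h * scale / net_side,
    )


def merge_module_predictions(
    slat_dets: Iterable[Detection],
    mlat_dets: Iterable[Detection],
    original_size: tuple[int, int],
    net_side: int = 608,
    cross_nms: float | None = None,
    letterbox: bool = False,
) -> list[MergedDetection]:
    """Union SLAT- and MLAT-pass detections on the original radiograph.

    Both input sets are network-normalized; outputs are tagged by module and
    expressed in original pixel units. Without ``cross_nms`` the union is
    returned as-is (both modules' boxes are displayed side by side); with a
    threshold, greedy NMS runs across the union before rescaling.
    """
    tagged = [
        Detection(d.box, d.class_id, d.confidence, "slat") for d in slat_dets
    ] + [Detection(d.box, d.class_id, d.confidence, "mlat") for d in mlat_dets]
    if cross_nms is not None:
        tagged = greedy_nms(tagged, cross_nms)
    return [
        MergedDetection(
            net_to_original(d.box, original_size, net_side, letterbox),
            d.class_id,
            d.confidence,
            d.module_tag,
        )
        for d in tagged
    ]
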