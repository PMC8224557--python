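"""Bounding boxes, class schemes and Darknet/YOLO label I/O.

Boxes follow the Darknet convention: center-based, normalized to the unit
square (``class cx cy w h`` per label line, floats in [0, 1]). Two class
schemes are in routine use: a two-class fracture-shape scheme
(shear / linear) and a six-class anatomic-region scheme (parasymphysis,
body, angle, ramus, condyle, coronoid).

Multi-box augmentation enlarges the effective annotation set: every fracture
is emitted with its reference box plus 0.7x- and 1.6x-scaled copies, three
boxes per fracture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BoundingBox",
    "Annotation",
    "ClassScheme",
    "SHAPE_SCHEME",
    "REGION_SCHEME",
    "MULTIBOX_FACTORS",
    "read_yolo_labels",
    "write_yolo_labels",
    "scale_box",
    "multi_box_augment",
]

#: Width/height factors of the two extra boxes emitted per fracture.
MULTIBOX_FACTORS: tuple[float, float] = (0.7, 1.6)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, center-based, in normalized image coordinates."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive: w={self.w} h={self.h}")
        x0, y0, x1, y1 = self.corners
        if x1 <= 0 or y1 <= 0 or x0 >= 1 or y0 >= 1:
            raise ValueError(f"box lies outside the unit square: {self}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) extent."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class Annotation:
    """A classified box; ``source_id`` groups the multi-box copies of one fracture."""

    box: BoundingBox
    class_id: int
    source_id: int = 0


@dataclass(frozen=True)
class ClassScheme:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in scheme {self.name!r}")
        if not labels:
            raise ValueError("empty class scheme")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def label(self, class_id: int) -> str:
        if not 0 <= class_id < len(self.labels):
            raise ValueError(
                f"class id {class_id} out of range for scheme {self.name!r}"
            )
        return self.labels[class_id]


#: Fracture-shape scheme (C = 2).
SHAPE_SCHEME = ClassScheme("shape", ("shear", "linear"))

#: Anatomic-region scheme (C = 6).
REGION_SCHEME = ClassScheme(
    "region",
    ("parasymphysis", "body", "angle", "ramus", "condyle", "coronoid"),
)


def read_yolo_labels(path: str | Path, scheme: ClassScheme) -> list[Annotation]:
    """Parse a Darknet label file (`class cx cy w h` per line).

    Each fracture gets a distinct ``source_id`` (its line index); an empty
    file yields an empty list. Malformed lines raise with their line number.
    """
    out: list[Annotation] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if not 0 <= cid < len(scheme):
            raise ValueError(
                f"{path}:{lineno}: class {cid} outside scheme "
                f"{scheme.name!r} (C={len(scheme)})"
            )
        for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{lineno}: {name}={v} outside [0, 1]")
        out.append(Annotation(BoundingBox(cx, cy, w, h), cid, source_id=len(out)))
    return out


def write_yolo_labels(annotations: Iterable[Annotation], path: str | Path) -> None:
    """Write annotations in input order, six-decimal fixed point."""
    lines = [
        f"{a.class_id} {a.box.cx:.6f} {a.box.cy:.6f} {a.box.w:.6f} {a.box.h:.6f}"
        for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def scale_box(box: BoundingBox, factor: float, clip: bool = True) -> BoundingBox:
    """Scale width and height by ``factor`` about the fixed center.

    With ``clip`` the result is intersected with the unit square and the
    center re-derived from the clipped extent; an empty intersection is an
    error.
    """
    if not factor > 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    scaled = BoundingBox(box.cx, box.cy, box.w * factor, box.h * factor)
    if not clip:
        return scaled
    x0, y0, x1, y1 = scaled.corners
    cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
    cx1, cy1 = min(x1, 1.0), min(y1, 1.0)
    if cx1 <= cx0 or cy1 <= cy0:
        raise ValueError(f"box empty after clipping: {box} scaled by {factor}")
    if (cx0, cy0, cx1, cy1) == (x0, y0, x1, y1):
        return scaled  # nothing clipped: keep the exact center/extent
    return BoundingBox((cx0 + cx1) / 2, (cy0 + cy1) / 2, cx1 - cx0, cy1 - cy0)


def multi_box_augment(
    annotations: Sequence[Annotation],
    factors: Sequence[float] = MULTIBOX_FACTORS,
    clip: bool = True,
) -> list[Annotation]:
    """Emit, per fracture, the reference box plus one scaled copy per factor.

    Copies share class and ``source_id`` with the original; with the default
    factors (0.7, 1.6) every fracture yields exactly three boxes, in the
    deterministic order original, 0.7x, 1.6x.
    """
    out: list[Annotation] = []
    for ann in annotations:
        out.append(ann)
        for f in factors:
            out.append(replace(ann, box=scale_box(ann.box, f, clip=clip)))
    return out
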