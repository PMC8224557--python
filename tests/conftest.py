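from __future__ import annotations

import numpy as np
import pytest

from panofrac.annotations import Annotation, BoundingBox
from panofrac.detection import Detection


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_box(rng: np.random.Generator) -> BoundingBox:
    w = rng.uniform(0.05, 0.4)
    h = rng.uniform(0.05, 0.4)
    cx = rng.uniform(w / 2, 1 - w / 2)
    cy = rng.uniform(h / 2, 1 - h / 2)
    return BoundingBox(cx, cy, w, h)


def random_detections(
    rng: np.random.Generator, n: int, n_classes: int = 2
) -> list[Detection]:
    return [
        Detection(
            random_box(rng),
            int(rng.integers(n_classes)),
            float(rng.uniform(0.05, 1.0)),
        )
        for _ in range(n)
    ]


def random_annotations(
    rng: np.random.Generator, n: int, n_classes: int = 6
) -> list[Annotation]:
    return [
        Annotation(random_box(rng), int(rng.integers(n_classes)), source_id=i)
        for i in range(n)
    ]
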