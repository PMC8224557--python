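"""Detector training configuration and training-plan arithmetic.

Holds the hyper-parameter set used to train the external YOLO v4 detector
(batch size, resolution, momentum, ...) and the epoch arithmetic that
relates the iteration budget to the training-set size: at batch 64 over
1080 images, 12 000 iterations correspond to 711 full epochs.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, fields
from fractions import Fraction

from .annotations import ClassScheme
from .detection import GridSpec, feature_map_shape

__all__ = [
    "TrainConfig",
    "training_plan",
    "training_plan_exact",
    "emit_detector_config",
    "parse_detector_config",
]


@dataclass(frozen=True)
class TrainConfig:
    """Detector training hyper-parameters (Darknet-style)."""

    batch_size: int = 64
    subdivision: int = 16
    resolution: int = 608
    momentum: float = 0.949
    decay: float = 0.0005
    learning_rate: float = 0.0001
    angle: int = 180
    saturation: float = 1.0
    exposure: float = 1.5
    hue: float = 0.0
    max_batches: int = 12000

    def __post_init__(self) -> None:
        for name in (
            "batch_size", "subdivision", "resolution", "momentum",
            "decay", "learning_rate", "exposure", "max_batches",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.resolution % 32:
            raise ValueError("resolution must be divisible by 32")


def training_plan_exact(
    max_batches: int, batch_size: int, n_training_images: int
) -> Fraction:
    """Exact epochs as a rational: iterations x batch / images."""
    if max_batches <= 0 or batch_size <= 0:
        raise ValueError("max_batches and batch_size must be positive")
    if n_training_images <= 0:
        raise ValueError("training-set size must be positive")
    return Fraction(max_batches * batch_size, n_training_images)


def training_plan(
    max_batches: int, batch_size: int, n_training_images: int
) -> int:
    """Whole epochs completed within the iteration budget (floor)."""
    return int(training_plan_exact(max_batches, batch_size, n_training_images))


def emit_detector_config(config: TrainConfig, scheme: ClassScheme) -> str:
    """Render the training parameters as deterministic key=value text.

    Includes the class count and the per-head filter depth 3 x (5 + C)
    the detector's prediction layers need for this scheme.
    """
    depth = feature_map_shape(GridSpec(s=1, b=3, c=len(scheme)))[2]
    lines = [f"{f.name}={getattr(config, f.name)!r}" for f in fields(config)]
    lines.append(f"classes={len(scheme)}")
    lines.append(f"filters={depth}")
    return "\n".join(lines) + "\n"


def parse_detector_config(text: str) -> TrainConfig:
    """Inverse of :func:`emit_detector_config` for the TrainConfig fields."""
    known = {f.name: f.type for f in fields(TrainConfig)}
    kwargs = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        if key in known:
            kwargs[key] = ast.literal_eval(value)
    return TrainConfig(**kwargs)
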