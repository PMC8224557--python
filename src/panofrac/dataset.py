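"""Training-set assembly: one source radiograph -> three enhanced variants.

Each source image is emitted as a gamma-modulated copy, a SLAT copy and an
MLAT copy (360 sources -> 1080 training images), with identical label files
per variant because the enhancements move no pixels. When multi-box
augmentation is enabled, each label file carries three boxes per fracture.
The layout follows the Darknet convention: ``images/`` and ``labels/`` with
matching stems plus a ``train.txt`` listing the image paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .annotations import Annotation, multi_box_augment, write_yolo_labels
from .imaging import GrayImage, save_image
from .tonemap import GAMMA_SET, MlatParams, SlatParams, enhance_image

__all__ = ["BuildConfig", "ManifestEntry", "DatasetManifest", "build_training_set"]

DEFAULT_VARIANTS: tuple[str, ...] = ("gamma", "slat", "mlat")


@dataclass(frozen=True)
class BuildConfig:
    """What the builder emits per source image."""

    variants: tuple[str, ...] = DEFAULT_VARIANTS
    gamma: float = GAMMA_SET[2]  # 1/0.3, the strongest darkening exponent
    multibox: bool = True
    slat_params: SlatParams = field(default_factory=SlatParams)
    mlat_params: MlatParams = field(default_factory=MlatParams)
    image_format: str = "png"


@dataclass(frozen=True)
class ManifestEntry:
    source_id: str
    variant: str
    image_path: str
    label_path: str


@dataclass(frozen=True)
class DatasetManifest:
    entries: tuple[ManifestEntry, ...]
    n_images: int
    n_boxes: int
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_images": self.n_images,
                "n_boxes": self.n_boxes,
                "seed": self.seed,
                "entries": [vars(e) for e in self.entries],
            },
            indent=2,
        )


def build_training_set(
    sources: Sequence[tuple[GrayImage, Sequence[Annotation]]],
    out_dir: str | Path,
    config: BuildConfig | None = None,
    source_ids: Sequence[str] | None = None,
    seed: int | None = None,
) -> DatasetManifest:
    """Emit enhanced image variants with shared label files.

    Parameters
    ----------
    sources
        (image, annotations) pairs, e.g. from the synthetic cohort generator
        or loaded from disk.
    out_dir
        Destination; ``images/``, ``labels/``, ``train.txt`` and
        ``manifest.json`` are created inside.
    config
        Variant set, gamma exponent, tone-mapping parameters, multi-box flag.
    """
    config = config or BuildConfig()
    out = Path(out_dir)
    img_dir = out / "images"
    lbl_dir = out / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)

    if source_ids is None:
        width = max(4, len(str(len(sources))))
        source_ids = [f"src{idx:0{width}d}" for idx in range(len(sources))]

    entries: list[ManifestEntry] = []
    n_boxes = 0
    train_list: list[str] = []
    for sid, (image, anns) in zip(source_ids, sources):
        labels = multi_box_augment(anns) if config.multibox else list(anns)
        for variant in config.variants:
            try:
                enhanced = enhance_image(
                    image,
                    variant,
                    gamma=config.gamma,
                    slat_params=config.slat_params,
                    mlat_params=config.mlat_params,
                )
                stem = f"{sid}_{variant}"
                img_path = img_dir / f"{stem}.{config.image_format}"
                lbl_path = lbl_dir / f"{stem}.txt"
                save_image(enhanced, img_path)
                write_yolo_labels(labels, lbl_path)
            except OSError as exc:
                raise OSError(f"while emitting source {sid!r}: {exc}") from exc
            entries.append(
                ManifestEntry(sid, variant, str(img_path), str(lbl_path))
            )
            train_list.append(str(img_path))
            n_boxes += len(labels)

    (out / "train.txt").write_text("\n".join(train_list) + "\n")
    manifest = DatasetManifest(tuple(entries), len(entries), n_boxes, seed=seed)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
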