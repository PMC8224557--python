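"""Synthetic panoramic-radiograph generator with ground-truth fractures.

Real panoramic radiographs of mandibular-fracture patients are not publicly
available, so every pipeline stage is exercised on synthetic stand-ins that
emulate the properties the enhancement stack targets: a dark, vignetted,
noisy background; a bright U-shaped jaw arc; and thin dark crack lines
crossing the arc at anatomically placed zones. Cracks come in two shapes
(straight "linear" vs stepped "shear") and six anatomic regions laid out
along the arc from the midline outwards: parasymphysis near the chin, then
body, angle, ramus, and condyle at the arc tips with the coronoid just
inside them. Every crack is returned with its exact bounding box, so the
generator doubles as a ground-truth source for the dataset builder and the
evaluation stack.

These images are deliberately schematic — no teeth, canals or soft-tissue
shadows — which is enough for geometry, counting and contrast properties
but says nothing about detection difficulty on clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .annotations import Annotation, BoundingBox, REGION_SCHEME, SHAPE_SCHEME
from .imaging import GrayImage

__all__ = [
    "PanoramicParams",
    "EPIDEMIOLOGICAL_WEIGHTS",
    "sample_regions",
    "generate_panoramic",
    "generate_cohort",
]

#: Relative fracture frequency per anatomic region, midpoints of the
#: reported clinical ranges (parasymphysis 30-50%, body 21-36%, angle
#: 15-26%, ramus 2-4%, condyle 20-26%, coronoid 1-2%), normalized.
EPIDEMIOLOGICAL_WEIGHTS: dict[str, float] = {
    "parasymphysis": 40.0,
    "body": 28.5,
    "angle": 20.5,
    "ramus": 3.0,
    "condyle": 23.0,
    "coronoid": 1.5,
}
_W_TOTAL = sum(EPIDEMIOLOGICAL_WEIGHTS.values())
EPIDEMIOLOGICAL_WEIGHTS = {
    k: v / _W_TOTAL for k, v in EPIDEMIOLOGICAL_WEIGHTS.items()
}

#: Arc-parameter band |t| occupied by each region (t = 0 midline, |t| = 1 tip).
_REGION_BANDS: dict[str, tuple[float, float]] = {
    "parasymphysis": (0.02, 0.18),
    "body": (0.25, 0.42),
    "angle": (0.48, 0.62),
    "ramus": (0.66, 0.78),
    "coronoid": (0.80, 0.87),
    "condyle": (0.88, 0.98),
}


@dataclass(frozen=True)
class PanoramicParams:
    """Geometry and photometry of one synthetic panoramic radiograph."""

    width: int = 256
    height: int = 128
    base_level: float = 40.0
    vignette_strength: float = 0.5
    arc_intensity: float = 180.0
    fracture_count: int = 1
    fracture_shape: str = "linear"  # "linear" or "shear"
    region_labels: tuple[str, ...] = REGION_SCHEME.labels
    crack_depth: float = 90.0
    noise_sd: float = 6.0
    seed: int = 0
    class_mode: str = "region"  # label boxes by region (C=6) or shape (C=2)

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("image must be at least 16x16")
        for name in ("base_level", "arc_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.fracture_count < 0:
            raise ValueError("fracture_count must be >= 0")
        if self.fracture_shape not in ("linear", "shear"):
            raise ValueError(f"unknown fracture shape {self.fracture_shape!r}")
        bad = set(self.region_labels) - set(REGION_SCHEME.labels)
        if bad:
            raise ValueError(f"unknown regions {sorted(bad)}")
        if self.class_mode not in ("region", "shape"):
            raise ValueError(f"unknown class mode {self.class_mode!r}")


def sample_regions(
    n: int,
    rng: np.random.Generator,
    weighted: bool = True,
    labels: Sequence[str] = REGION_SCHEME.labels,
) -> list[str]:
    """Draw fracture regions, by clinical frequency or uniformly."""
    labels = list(labels)
    if weighted:
        w = np.array([EPIDEMIOLOGICAL_WEIGHTS[lab] for lab in labels])
        p = w / w.sum()
    else:
        p = np.full(len(labels), 1.0 / len(labels))
    return list(rng.choice(labels, size=n, p=p))


def _arc_geometry(params: PanoramicParams):
    """Jaw arc as a parametric curve x(t), y(t), t in [-1, 1], chin at t=0."""
    w, h = params.width, params.height
    half_span = 0.42 * w
    y_chin = 0.78 * h
    depth = 0.52 * h

    def point(t: float) -> tuple[float, float]:
        return (w / 2 + t * half_span, y_chin - depth * t * t)

    def normal(t: float) -> tuple[float, float]:
        # unit normal to (dx/dt, dy/dt) = (half_span, -2*depth*t)
        dx, dy = half_span, -2 * depth * t
        n = np.hypot(dx, dy)
        return (-dy / n, dx / n)

    radius = max(3.0, 0.055 * h)
    return point, normal, radius


def _distance_to_points(shape, xs, ys) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest of the given points."""
    mask = np.ones(shape, dtype=bool)
    ix = np.clip(np.rint(ys).astype(int), 0, shape[0] - 1)
    jx = np.clip(np.rint(xs).astype(int), 0, shape[1] - 1)
    mask[ix, jx] = False
    return ndimage.distance_transform_edt(mask)


def _render_crack(
    params: PanoramicParams,
    point,
    normal,
    radius: float,
    t_abs: float,
    side: int,
    shape: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, BoundingBox]:
    """Crack pixel mask (distance field) and its normalized bounding box."""
    t = side * t_abs
    x0, y0 = point(t)
    nx, ny = normal(t)
    length = 2.3 * radius
    samples = np.linspace(-length / 2, length / 2, 48)
    jitter = rng.normal(0.0, 0.35, size=samples.size)
    if shape == "shear":
        # displaced step: the two crack halves are offset laterally
        step = np.where(samples < 0, -1.0, 1.0) * 0.45 * radius
    else:
        step = np.zeros_like(samples)
    # lateral direction = tangent of the arc (perpendicular to the normal)
    tx, ty = ny, -nx
    xs = x0 + nx * samples + tx * (step + jitter)
    ys = y0 + ny * samples + ty * (step + jitter)

    dist = _distance_to_points((params.height, params.width), xs, ys)
    crack = np.exp(-0.5 * (dist / 1.1) ** 2)  # ~1-2 px wide dark line

    pad = 2.0
    bx0 = max((xs.min() - pad) / params.width, 0.0)
    bx1 = min((xs.max() + pad) / params.width, 1.0)
    by0 = max((ys.min() - pad) / params.height, 0.0)
    by1 = min((ys.max() + pad) / params.height, 1.0)
    box = BoundingBox(
        (bx0 + bx1) / 2, (by0 + by1) / 2, bx1 - bx0, by1 - by0
    )
    return crack, box


def generate_panoramic(
    params: PanoramicParams,
    region_choices: Sequence[str] | None = None,
) -> tuple[GrayImage, list[Annotation]]:
    """Render one synthetic panoramic radiograph with exact annotations.

    ``region_choices`` overrides the random region draw (used by the cohort
    generator for epidemiologically weighted sampling); its length must
    equal ``params.fracture_count``. Identical params give bit-identical
    output. Each fracture occupies a distinct (region, side) zone; asking
    for more fractures than there are free zones is an error.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.width, params.height
    point, normal, radius = _arc_geometry(params)

    # dark vignetted background
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d2 = ((xx - w / 2) / (w / 2)) ** 2 + ((yy - h / 2) / (h / 2)) ** 2
    bg = params.base_level * (1.0 - params.vignette_strength * d2 / 2.0)

    # bright jaw arc with a Gaussian cross-profile
    ts = np.linspace(-1.0, 1.0, 4 * w)
    pts = np.array([point(t) for t in ts])
    arc_dist = _distance_to_points((h, w), pts[:, 0], pts[:, 1])
    arc_profile = np.exp(-0.5 * (arc_dist / radius) ** 2)
    img = bg + (params.arc_intensity - bg) * arc_profile

    # place fractures in distinct (region, side) zones
    zones = [(lab, s) for lab in params.region_labels for s in (-1, 1)]
    if params.fracture_count > len(zones):
        raise ValueError(
            f"{params.fracture_count} fractures requested but only "
            f"{len(zones)} placeable zones"
        )
    if region_choices is not None:
        if len(region_choices) != params.fracture_count:
            raise ValueError("region_choices length must match fracture_count")
        chosen: list[tuple[str, int]] = []
        used = set()
        for lab in region_choices:
            sides = [s for s in (-1, 1) if (lab, s) not in used]
            if not sides:
                raise ValueError(f"both {lab!r} zones already occupied")
            s = int(rng.choice(sides))
            chosen.append((lab, s))
            used.add((lab, s))
    else:
        idx = rng.choice(len(zones), size=params.fracture_count, replace=False)
        chosen = [zones[i] for i in idx]

    annotations: list[Annotation] = []
    for fid, (lab, side) in enumerate(chosen):
        lo, hi = _REGION_BANDS[lab]
        t_abs = rng.uniform(lo, hi)
        crack, box = _render_crack(
            params, point, normal, radius, t_abs, side, params.fracture_shape, rng
        )
        img = img - params.crack_depth * crack
        if params.class_mode == "region":
            cid = REGION_SCHEME.labels.index(lab)
        else:
            cid = SHAPE_SCHEME.labels.index(params.fracture_shape)
        annotations.append(Annotation(box, cid, source_id=fid))

    img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return GrayImage(np.clip(img, 0.0, 255.0)), annotations


def generate_cohort(
    n: int,
    params: PanoramicParams | None = None,
    seed: int = 0,
    epidemiological_weights: bool = False,
) -> list[tuple[GrayImage, list[Annotation]]]:
    """Draw ``n`` independent synthetic radiographs.

    Per-image seeds derive from the master seed, so the cohort is fully
    reproducible. With ``epidemiological_weights`` fracture regions follow
    the clinical frequency distribution (parasymphysis most common);
    otherwise the zone draw is uniform.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    params = params or PanoramicParams()
    master = np.random.default_rng(seed)
    region_rng = np.random.default_rng(master.integers(2**31))
    out = []
    for _ in range(n):
        img_seed = int(master.integers(2**31))
        p = replace(params, seed=img_seed)
        choices = None
        if epidemiological_weights:
            choices = sample_regions(
                p.fracture_count, region_rng, labels=p.region_labels
            )
        out.append(generate_panoramic(p, region_choices=choices))
    return out
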