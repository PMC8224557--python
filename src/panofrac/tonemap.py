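"""Radiograph enhancement operators: gamma modulation, SLAT and MLAT.

Panoramic radiographs are globally dark with uneven illumination, which
hides thin fracture lines. Three pixel-wise enhancements address this:

* **gamma modulation** — a global power law ``O = (I/255)^gamma * 255``;
  exponents above 1 darken mid-tones so fracture lines stay distinct.
* **SLAT** (single-scale luminance adaptation transform) — a local tone
  mapping. The adaptation luminance ``Lan`` (Gaussian surround of the
  normalized luminance ``Ln``) drives, per pixel, a minimum and maximum
  luminance level and a local visual gamma fitted from Bartelson-Breneman
  brightness functions. The normalized response
  ``f = |(Ln - Lmin)/(Lmax - Lmin)|^gamma`` is then stretched by a global
  gain/offset so the output spans the full intensity range.
* **MLAT** (multi-scale LAT) — a weighted sum of SLATs at several surround
  scales (default 15, 80, 250 px), trading off local detail against global
  tone rendition.

All three are geometry-preserving: no pixel moves, so bounding-box
annotations remain valid on every enhanced variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import (
    INTENSITY_RANGE,
    GrayImage,
    LuminanceField,
    gaussian_surround,
    normalize_luminance,
)

__all__ = [
    "GAMMA_SET",
    "DEFAULT_MLAT_SCALES",
    "SlatParams",
    "MlatParams",
    "gamma_modulate",
    "adaptation_levels",
    "visual_gamma",
    "slat",
    "mlat",
]

#: Global gamma exponents used for luminance augmentation of training data.
GAMMA_SET: tuple[float, ...] = (1.0, 1 / 0.6, 1 / 0.3)

#: Surround scales (sigma, pixels) of the multi-scale transform.
DEFAULT_MLAT_SCALES: tuple[float, ...] = (15.0, 80.0, 250.0)


@dataclass(frozen=True)
class SlatParams:
    """Parameters of the single-scale transform.

    ``surround_scale`` is the Gaussian sigma in pixels (default 80, the middle
    multi-scale value). ``corrected_offset_sign`` selects the offset
    ``-Rcs*fmin/(fmax-fmin)``, which maps the response exactly onto
    ``[0, rcs]``; the positive-sign variant is kept for comparison.
    """

    surround_scale: float = 80.0
    rcs: float = INTENSITY_RANGE
    flat_epsilon: float = 1e-12
    corrected_offset_sign: bool = True

    def __post_init__(self) -> None:
        if not self.surround_scale > 0:
            raise ValueError("surround_scale must be positive")
        if not self.rcs > 0:
            raise ValueError("rcs must be positive")
        if not self.flat_epsilon > 0:
            raise ValueError("flat_epsilon must be positive")


@dataclass(frozen=True)
class MlatParams:
    """Scales and convex weights of the multi-scale transform."""

    scales: tuple[float, ...] = DEFAULT_MLAT_SCALES
    weights: tuple[float, ...] | None = None
    slat: SlatParams = field(default_factory=SlatParams)

    def __post_init__(self) -> None:
        scales = tuple(float(s) for s in self.scales)
        if len(scales) < 1 or any(s <= 0 for s in scales):
            raise ValueError(f"need >= 1 positive scales, got {scales}")
        if self.weights is None:
            weights = tuple(1.0 / len(scales) for _ in scales)
        else:
            weights = tuple(float(w) for w in self.weights)
        if len(weights) != len(scales):
            raise ValueError(
                f"{len(weights)} weights for {len(scales)} scales"
            )
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1, got {sum(weights)!r}")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "weights", weights)


def gamma_modulate(image: GrayImage, gamma: float) -> GrayImage:
    """Apply the global power law ``O = (I/255)^gamma * 255``."""
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    out = (image.pixels / INTENSITY_RANGE) ** gamma * INTENSITY_RANGE
    return GrayImage(np.clip(out, 0.0, INTENSITY_RANGE))


def adaptation_levels(lan):
    """Minimum and maximum luminance levels at adaptation luminance ``lan``.

    ``Lmin = 0.0212 + 0.0185 * Lan^1.0314`` and
    ``Lmax = 25.83 + 30.82 * Lan^0.6753``; ``Lmax > Lmin`` for all
    ``lan >= 0``. Accepts scalars or arrays.
    """
    lan = np.asarray(lan, dtype=np.float64)
    if np.any(lan < 0):
        raise ValueError("adaptation luminance must be non-negative")
    lmin = 0.0212 + 0.0185 * lan**1.0314
    lmax = 25.83 + 30.82 * lan**0.6753
    return lmin, lmax


def visual_gamma(lan):
    """Local visual gamma ``0.444 + 0.045 * ln(Lan + 0.6034)``.

    Strictly increasing in ``lan``; accepts scalars or arrays.
    """
    lan = np.asarray(lan, dtype=np.float64)
    if np.any(lan < 0):
        raise ValueError("adaptation luminance must be non-negative")
    return 0.444 + 0.045 * np.log(lan + 0.6034)


def _slat_response(lum: LuminanceField, scale: float) -> np.ndarray:
    """Per-pixel normalized response f before the global gain/offset."""
    ln = lum.values
    lan = gaussian_surround(lum, scale).values
    lmin, lmax = adaptation_levels(lan)
    gamma = visual_gamma(lan)
    return np.abs((ln - lmin) / (lmax - lmin)) ** gamma


def slat(lum: LuminanceField, params: SlatParams | None = None) -> GrayImage:
    """Single-scale luminance adaptation transform.

    A flat field carries no range to stretch (``fmax == fmin``); it maps to
    uniform mid-gray ``rcs/2``.
    """
    params = params or SlatParams()
    f = _slat_response(lum, params.surround_scale)
    fmin, fmax = float(f.min()), float(f.max())
    if fmax - fmin < params.flat_epsilon:
        return GrayImage(np.full(lum.shape, params.rcs / 2.0))
    gain = params.rcs / (fmax - fmin)
    offset = params.rcs * fmin / (fmax - fmin)
    if params.corrected_offset_sign:
        offset = -offset
    out = gain * f + offset
    return GrayImage(np.clip(out, 0.0, params.rcs))


def mlat(lum: LuminanceField, params: MlatParams | None = None) -> GrayImage:
    """Multi-scale transform: convex combination of per-scale SLAT outputs.

    Each scale runs a complete SLAT pass with its own global gain/offset.
    """
    params = params or MlatParams()
    acc = np.zeros(lum.shape)
    for w, s in zip(params.weights, params.scales):
        sp = SlatParams(
            surround_scale=s,
            rcs=params.slat.rcs,
            flat_epsilon=params.slat.flat_epsilon,
            corrected_offset_sign=params.slat.corrected_offset_sign,
        )
        acc += w * slat(lum, sp).pixels
    return GrayImage(np.clip(acc, 0.0, params.slat.rcs))


def enhance_image(image: GrayImage, op: str, *, gamma: float = 1.0,
                  slat_params: SlatParams | None = None,
                  mlat_params: MlatParams | None = None) -> GrayImage:
    """Dispatch helper used by the dataset builder and the CLI."""
    if op == "gamma":
        return gamma_modulate(image, gamma)
    lum = normalize_luminance(image)
    if op == "slat":
        return slat(lum, slat_params)
    if op == "mlat":
        return mlat(lum, mlat_params)
    raise ValueError(f"unknown enhancement op {op!r}")
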