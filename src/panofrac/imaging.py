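"""Image containers and luminance-adaptation primitives.

Panoramic radiographs are handled as 8-bit grayscale rasters. All tone-mapping
math happens on a *luminance field*: the intensity channel rescaled to the
0-100 range on which the luminance-adaptation constants are calibrated
(adaptation luminance under a 100 cd/m^2 surround). The local adaptation
state of the observer is approximated by a Gaussian low-pass "surround"
of that field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "LuminanceField",
    "load_image",
    "save_image",
    "normalize_luminance",
    "to_gray_image",
    "gaussian_surround",
]

#: Intensity range of 8-bit grayscale, the "selected color space" range Rcs.
INTENSITY_RANGE = 255.0

#: Ceiling of the normalized luminance scale.
LUMINANCE_CEIL = 100.0

# Standard Rec.601 luma weights for collapsing RGB input to gray.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale intensity grid with values in [0, 255].

    Pixels are stored as float64 so that tone-mapped results keep sub-integer
    precision; :meth:`to_uint8` rounds for disk output.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected a non-empty 2-D grid, got shape {px.shape}")
        if px.min() < 0 or px.max() > INTENSITY_RANGE:
            raise ValueError(
                f"intensities outside [0, {INTENSITY_RANGE:g}]: "
                f"min={px.min():g} max={px.max():g}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class LuminanceField:
    """Normalized luminance grid on the [0, 100] scale."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"expected a non-empty 2-D grid, got shape {v.shape}")
        # tiny negative/overshoot from float arithmetic is clamped, real
        # violations are rejected
        if v.min() < -1e-9 or v.max() > LUMINANCE_CEIL + 1e-9:
            raise ValueError(
                f"luminance outside [0, {LUMINANCE_CEIL:g}]: "
                f"min={v.min():g} max={v.max():g}"
            )
        object.__setattr__(self, "values", np.clip(v, 0.0, LUMINANCE_CEIL))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def load_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF raster as an 8-bit-scale grayscale image.

    Multi-channel input is collapsed with Rec.601 luma weights; integer
    inputs deeper than 8 bits are rescaled linearly so full scale maps to 255.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image rank {arr.ndim} in {path}")
    arr = arr.astype(np.float64)
    if arr.max() > INTENSITY_RANGE:
        # deeper-than-8-bit input: rescale by dtype full scale
        info_max = np.iinfo(np.asarray(iio.imread(path)).dtype).max
        arr = arr * (INTENSITY_RANGE / info_max)
    return GrayImage(arr)


def save_image(image: GrayImage, path: str | Path) -> None:
    """Write an image as an 8-bit raster (format chosen by extension)."""
    iio.imwrite(Path(path), image.to_uint8())


def normalize_luminance(image: GrayImage) -> LuminanceField:
    """Rescale intensities linearly from [0, 255] to the [0, 100] scale."""
    return LuminanceField(image.pixels * (LUMINANCE_CEIL / INTENSITY_RANGE))


def to_gray_image(lum: LuminanceField) -> GrayImage:
    """Inverse of :func:`normalize_luminance` (exact up to float arithmetic)."""
    return GrayImage(lum.values * (INTENSITY_RANGE / LUMINANCE_CEIL))


def gaussian_surround(lum: LuminanceField, scale: float) -> LuminanceField:
    """Estimate the adaptation luminance by Gaussian low-pass filtering.

    Parameters
    ----------
    lum
        Normalized luminance field.
    scale
        Standard deviation of the Gaussian in pixels. The kernel is truncated
        at 3 sigma and normalized to unit sum; boundaries are handled by
        reflection, so a uniform field is a fixed point and the output range
        never exceeds the input range.
    """
    if not scale > 0:
        raise ValueError(f"surround scale must be positive, got {scale}")
    if int(3.0 * scale + 0.5) < 1:
        # sub-half-pixel kernel degenerates to the identity
        return LuminanceField(lum.values.copy())
    out = ndimage.gaussian_filter(lum.values, sigma=scale, mode="reflect", truncate=3.0)
    return LuminanceField(out)
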