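"""Grayscale image container, raster I/O, and reference-based quality metrics.

All images in this package are 2-D fields of intensities normalized to the
unit interval.  PNG and TIFF rasters are rescaled on load by the maximum
representable value of their sample type (255 for 8-bit, 65535 for 16-bit),
so that MSE and PSNR are always computed on the [0, 1] scale with MAX = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Union

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "QualityMetrics",
    "load_image",
    "save_image",
    "mse",
    "psnr",
    "as_pixels",
]

#: luminance weights for RGB -> gray conversion (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])

# tolerance for float round-off when validating the [0, 1] intensity range;
# values inside the band are snapped to the exact bound
_RANGE_EPS = 1e-9


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 1].

    Parameters
    ----------
    pixels
        2-D array of intensities.  Converted to a C-contiguous float64
        array on construction; values must lie in [0, 1] (a round-off
        band of 1e-9 beyond either bound is snapped to the bound).
    """

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite intensities")
        lo, hi = arr.min(), arr.max()
        if lo < -_RANGE_EPS or hi > 1.0 + _RANGE_EPS:
            raise ValueError(
                f"intensities must lie in [0, 1]; got range [{lo}, {hi}]"
            )
        if lo < 0.0 or hi > 1.0:
            arr = np.clip(arr, 0.0, 1.0)
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


ImageLike = Union[GrayImage, np.ndarray]


def as_pixels(image: ImageLike) -> np.ndarray:
    """Return the float64 pixel array behind ``image`` (validating it)."""
    if isinstance(image, GrayImage):
        return image.pixels
    return GrayImage(np.asarray(image)).pixels


def load_image(path: Union[str, PathLike]) -> GrayImage:
    """Load a PNG/TIFF raster as a normalized grayscale image.

    Integer samples are divided by the maximum representable value of
    their dtype; RGB(A) input is converted to luminance first.  Floating
    point rasters are taken as already being on the [0, 1] scale.
    """
    raw = iio.imread(path)
    if raw.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    arr = np.asarray(raw)
    if arr.ndim == 3:  # RGB or RGBA -> luminance, alpha ignored
        arr = arr[..., :3] @ _LUMA
        scale_dtype = raw.dtype
    elif arr.ndim == 2:
        scale_dtype = arr.dtype
    else:
        raise ValueError(f"unsupported image dimensionality: {arr.ndim}")
    arr = arr.astype(np.float64)
    if np.issubdtype(scale_dtype, np.integer):
        arr /= np.iinfo(scale_dtype).max
    return GrayImage(np.clip(arr, 0.0, 1.0))


def save_image(
    image: ImageLike, path: Union[str, PathLike], *, bit_depth: int = 16
) -> None:
    """Write ``image`` as a PNG/TIFF raster at the given bit depth.

    A save/load round trip reproduces intensities within one quantization
    step (1/255 at 8 bits, 1/65535 at 16 bits).
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    arr = as_pixels(image)
    maxval = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quantized = np.round(arr * maxval).astype(dtype)
    iio.imwrite(path, quantized)


def mse(reference: ImageLike, test: ImageLike) -> float:
    """Mean squared error between two equally shaped images."""
    ref, tst = as_pixels(reference), as_pixels(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    return float(np.mean((ref - tst) ** 2))


def psnr(reference: ImageLike, test: ImageLike) -> float:
    """Peak signal-to-noise ratio in dB, with MAX = 1.

    Returns ``math.inf`` for identical images (MSE = 0); this sentinel is
    part of the contract, not an error.
    """
    err = mse(reference, test)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / err)


@dataclass(frozen=True)
class QualityMetrics:
    """MSE / PSNR pair for one denoised image against its clean reference."""

    mse: float
    psnr: float

    @classmethod
    def compare(cls, reference: ImageLike, test: ImageLike) -> "QualityMetrics":
        return cls(mse=mse(reference, test), psnr=psnr(reference, test))

    def to_dict(self) -> dict:
        return {"mse": self.mse, "psnr": self.psnr}
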