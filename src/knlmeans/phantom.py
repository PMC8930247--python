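"""Synthetic organ phantom, multiplicative speckle simulation, noise estimation.

The phantom stands in for renal B-mode ultrasound: a piecewise-constant
field of nested ellipses on a background (background / parenchyma / sinus
for three classes), jittered by a geometry seed.  Speckle is simulated as
multiplicative Gaussian noise J = I * (1 + n), n ~ N(0, sigma^2) i.i.d.,
clipped to [0, 1] — signal-dependent, with E[J] = I and Var[J] = I^2 sigma^2
away from the clip bounds.  This is a simulation convention, not a physical
acoustic model (no point-spread function, scan conversion or attenuation).

The noise standard deviation estimator supplies the filter coefficient h of
the non-local-means filters: the Laplacian pseudo-residual of the image is
computed on interior pixels and scaled by a robust (median absolute
deviation) estimate, so that step edges between tissue classes do not
inflate the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import convolve2d
from scipy.stats import median_abs_deviation

from .image import GrayImage, ImageLike, as_pixels

__all__ = [
    "SpeckleParams",
    "PhantomSpec",
    "make_phantom",
    "add_speckle",
    "estimate_noise_std",
]

# Laplacian pseudo-residual stencil; annihilates constants and linear ramps.
# For i.i.d. noise of std sigma the residual has std 6*sigma (sqrt of the
# sum of squared coefficients).
_RESIDUAL_STENCIL = np.array(
    [[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]]
)
_RESIDUAL_NORM = 6.0


@dataclass(frozen=True)
class SpeckleParams:
    """Multiplicative speckle model: noise std ``sigma`` and RNG ``seed``."""

    sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the piecewise-constant phantom.

    ``class_intensities`` lists the tissue levels outside-in: background
    first, then one nested ellipse per remaining class.  At least two
    distinct classes are required (clustering a single level is
    meaningless), and every level must lie in [0, 1].
    """

    height: int = 128
    width: int = 128
    class_intensities: Sequence[float] = (0.2, 0.5, 0.8)
    geometry_seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        levels = tuple(float(v) for v in self.class_intensities)
        if len(levels) < 2:
            raise ValueError("need at least 2 intensity classes")
        if len(set(levels)) != len(levels):
            raise ValueError("class intensities must be distinct")
        if min(levels) < 0.0 or max(levels) > 1.0:
            raise ValueError("class intensities must lie in [0, 1]")
        object.__setattr__(self, "class_intensities", levels)


def make_phantom(spec: PhantomSpec) -> GrayImage:
    """Render the nested-ellipse phantom described by ``spec``.

    Deterministic given the spec (the geometry seed drives center and axis
    jitter).  Each intensity class covers at least 5% of the pixels; a
    spec too small or too crowded to satisfy that raises ``ValueError``.
    """
    levels = spec.class_intensities
    k = len(levels)
    rng = np.random.default_rng(spec.geometry_seed)
    h, w = spec.height, spec.width

    # common jittered center; per-ellipse +-2% axis jitter keeps nesting
    cy = (h - 1) / 2.0 * (1.0 + 0.04 * rng.uniform(-1, 1))
    cx = (w - 1) / 2.0 * (1.0 + 0.04 * rng.uniform(-1, 1))
    yy, xx = np.mgrid[0:h, 0:w]

    img = np.full((h, w), levels[0])
    for c in range(1, k):
        # equal-area spacing of the nested ellipses
        frac = 0.88 * np.sqrt((k - c) / (k - 1))
        ry = frac * h / 2.0 * rng.uniform(0.98, 1.02)
        rx = frac * w / 2.0 * rng.uniform(0.98, 1.02)
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img[inside] = levels[c]

    counts = {lvl: int(np.count_nonzero(img == lvl)) for lvl in levels}
    min_frac = min(counts.values()) / (h * w)
    if min_frac < 0.05:
        raise ValueError(
            f"phantom {h}x{w} too small for {k} classes: smallest region "
            f"covers {min_frac:.1%} of pixels (< 5%)"
        )
    return GrayImage(img)


def add_speckle(image: ImageLike, params: SpeckleParams) -> GrayImage:
    """Corrupt ``image`` with multiplicative Gaussian speckle.

    noisy = clip(clean * (1 + n), 0, 1) with n ~ N(0, sigma^2) drawn from
    ``default_rng(params.seed)``; bit-for-bit reproducible per seed.
    """
    clean = as_pixels(image)
    if params.sigma == 0.0:
        return GrayImage(clean.copy())
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(clean.shape)
    noisy = clean * (1.0 + params.sigma * noise)
    return GrayImage(np.clip(noisy, 0.0, 1.0))


def estimate_noise_std(image: ImageLike) -> float:
    """Robust estimate of the additive-equivalent noise standard deviation.

    Convolves the image with the 3x3 Laplacian pseudo-residual stencil
    (interior pixels only) and scales the residuals' normal-consistent MAD
    by the stencil norm.  The residual operator annihilates constants and
    ramps, and the median scale suppresses the sparse large residuals that
    tissue-boundary edges produce, so the estimate tracks the noise rather
    than the structure.
    """
    arr = as_pixels(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for noise estimation")
    residual = convolve2d(arr, _RESIDUAL_STENCIL, mode="valid")
    mad = median_abs_deviation(residual, axis=None, scale="normal")
    return float(mad) / _RESIDUAL_NORM
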