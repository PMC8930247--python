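"""Non-local-means speckle filtering, plain and gradient-augmented.

Each output pixel is a convex combination of the candidate pixels in its
search window,

    S(w(i)) = sum_j T(i, j) w(j),
    T(i, j) = exp(-d(i, j) / (a^2 h^2)) / K(i),
    K(i)    = sum_j exp(-d(i, j) / (a^2 h^2)),

where d(i, j) is the Gaussian-kernel-weighted squared L2 distance between
the patches centered at i and j.  The gradient-augmented variant multiplies
the intensity patch distance by the analogous distance between
gradient-magnitude patches before exponentiation, which shrinks the weights
of candidates that disagree in local structure and so preserves edges and
fine detail; when either factor vanishes the exponent is zero and the
weight is maximal.

The filter coefficient h defaults to the image's own estimated noise
standard deviation (times a tunable factor ``h_lambda``).  Patches and
gradients use symmetric (mirror) padding at the borders.  Candidate sets
never include out-of-image positions, and the candidate j = i always
carries weight exp(0) = 1, so the normalizer K(i) >= 1 is never degenerate.

``naive_oracle_denoise`` is a literal per-pixel-pair transcription of the
weighted-average equations over the whole image, kept free of windowing or
vectorized shortcuts; the production filters are checked against it exactly
on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import correlate2d

from .image import GrayImage, ImageLike, as_pixels
from .phantom import estimate_noise_std

__all__ = [
    "PatchConfig",
    "WeightField",
    "patch_distance",
    "gradient_magnitude",
    "nlmeans_denoise",
    "nlmeans_gradient_denoise",
    "naive_oracle_denoise",
    "weight_field",
    "resolve_h",
]

# floor for an auto-resolved h on a (near-)constant image; any positive
# value leaves constant images as exact fixed points
_H_FLOOR = 1e-6

#: largest image side accepted by the quadratic-cost oracle
ORACLE_MAX_SIDE = 32


@dataclass(frozen=True)
class PatchConfig:
    """Hyperparameters of the non-local-means filters.

    Parameters
    ----------
    patch_radius
        Half-width of the comparison patch; the patch is
        ``(2r+1) x (2r+1)`` pixels.
    search_radius
        Half-width of the candidate search window (Chebyshev radius).
        ``None`` is the whole-image sentinel: every pixel is a candidate,
        matching the integral over the full image domain.
    gaussian_sigma
        Std (pixels) of the Gaussian patch-weighting kernel, truncated at
        the patch radius and renormalized to sum 1.  ``None`` defaults to
        ``patch_radius / 2``.
    h
        Filter coefficient (intensity units).  ``None`` means "resolve
        from the image": ``h = h_lambda * estimate_noise_std(image)``.
    h_lambda
        Proportionality factor applied to the estimated noise std when
        ``h`` is auto-resolved.  The expected patch distance between two
        same-tissue patches is about twice the noise variance, so h must
        exceed the noise std for those candidates to retain O(1) weight;
        the default of 3 keeps same-class exponents below ~1 while a
        tissue-contrast step of a few noise stds is still suppressed.
    a
        Gaussian std appearing in the ``a^2 h^2`` exponent denominator.
    use_gradient
        Select the gradient-augmented weight (used by the oracle, the
        per-pixel weight field, and the CLI dispatch; the two public
        denoise functions fix the variant themselves).
    """

    patch_radius: int = 2
    search_radius: Optional[int] = 10
    gaussian_sigma: Optional[float] = None
    h: Optional[float] = None
    h_lambda: float = 3.0
    a: float = 1.0
    use_gradient: bool = False

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.search_radius is not None and self.search_radius < self.patch_radius:
            raise ValueError("search_radius must be >= patch_radius (or None)")
        if self.gaussian_sigma is not None and self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be > 0")
        if self.h_lambda <= 0:
            raise ValueError("h_lambda must be > 0")
        if self.a <= 0:
            raise ValueError("a must be > 0")

    @property
    def kernel_sigma(self) -> float:
        return (
            self.gaussian_sigma
            if self.gaussian_sigma is not None
            else self.patch_radius / 2.0
        )


@dataclass(frozen=True)
class WeightField:
    """The normalized weights of one target pixel over its candidates."""

    pixel: tuple[int, int]
    candidates: np.ndarray  # (M, 2) int array of (row, col)
    weights: np.ndarray  # (M,) normalized, sums to 1
    normalizer: float  # K(i), the pre-normalization weight sum


def resolve_h(image: ImageLike, config: PatchConfig) -> float:
    """Concrete filter coefficient for ``image`` under ``config``."""
    if config.h is not None:
        return config.h
    return max(config.h_lambda * estimate_noise_std(image), _H_FLOOR)


def _patch_kernel(config: PatchConfig) -> np.ndarray:
    """Gaussian patch kernel, truncated at the radius, normalized to sum 1."""
    r = config.patch_radius
    ax = np.arange(-r, r + 1, dtype=np.float64)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    kern = np.exp(-(yy**2 + xx**2) / (2.0 * config.kernel_sigma**2))
    return kern / kern.sum()


def patch_distance(
    image: ImageLike,
    i: tuple[int, int],
    j: tuple[int, int],
    config: PatchConfig,
) -> float:
    """Gaussian-weighted squared L2 distance between the patches at i and j.

    ``sum_l G(l) * (w(i+l) - w(j+l))^2`` over patch offsets ``l``, with the
    kernel G normalized to sum 1 and symmetric padding at the borders.
    """
    arr = as_pixels(image)
    r = config.patch_radius
    padded = np.pad(arr, r, mode="symmetric")
    kern = _patch_kernel(config)
    pi = padded[i[0] : i[0] + 2 * r + 1, i[1] : i[1] + 2 * r + 1]
    pj = padded[j[0] : j[0] + 2 * r + 1, j[1] : j[1] + 2 * r + 1]
    return float(np.sum(kern * (pi - pj) ** 2))


def gradient_magnitude(image: ImageLike) -> np.ndarray:
    """Per-pixel magnitude of the mirrored central-difference gradient.

    Central differences on the symmetric-padded image; at a border the
    mirrored neighbor collapses the stencil to a half-weight one-sided
    difference.  Exact for linear ramps in the interior.
    """
    arr = as_pixels(image)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("gradient needs an image of at least 2x2")
    padded = np.pad(arr, 1, mode="symmetric")
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return np.hypot(gy, gx)


def _shift_bounds(delta: int, n: int) -> tuple[int, int]:
    """Index range [lo, hi) of target pixels whose candidate at offset
    ``delta`` stays inside an axis of length ``n``."""
    return max(0, -delta), n - max(0, delta)


def _denoise_engine(
    arr: np.ndarray,
    config: PatchConfig,
    h: float,
    *,
    use_gradient: bool,
    labels: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Windowed NL-Means via candidate-offset accumulation.

    For each search offset t the patch-distance field d(i, i+t) is computed
    for all target pixels at once by correlating the squared difference of
    the padded image with its shifted copy against the patch kernel; the
    per-offset weights are accumulated into the weighted average.  This is
    algebraically identical to the per-pixel definition (the oracle), just
    reordered.  ``labels`` restricts candidates to the target pixel's own
    cluster; out-of-image candidates are always excluded.
    """
    hgt, wid = arr.shape
    r = config.patch_radius
    kern = _patch_kernel(config)
    denom = (config.a * h) ** 2

    padded = np.pad(arr, r, mode="symmetric")
    grad_padded = None
    if use_gradient:
        grad_padded = np.pad(gradient_magnitude(arr), r, mode="symmetric")

    if config.search_radius is None:
        dys = range(-(hgt - 1), hgt)
        dxs = range(-(wid - 1), wid)
    else:
        s = config.search_radius
        dys = range(-s, s + 1)
        dxs = range(-s, s + 1)

    num = np.zeros_like(arr)
    den = np.zeros_like(arr)
    for dy in dys:
        r0, r1 = _shift_bounds(dy, hgt)
        if r0 >= r1:
            continue
        for dx in dxs:
            c0, c1 = _shift_bounds(dx, wid)
            if c0 >= c1:
                continue
            tgt = padded[r0 : r1 + 2 * r, c0 : c1 + 2 * r]
            cand = padded[r0 + dy : r1 + dy + 2 * r, c0 + dx : c1 + dx + 2 * r]
            dist = correlate2d((tgt - cand) ** 2, kern, mode="valid")
            if use_gradient:
                gt = grad_padded[r0 : r1 + 2 * r, c0 : c1 + 2 * r]
                gc = grad_padded[
                    r0 + dy : r1 + dy + 2 * r, c0 + dx : c1 + dx + 2 * r
                ]
                dist = dist * correlate2d((gt - gc) ** 2, kern, mode="valid")
            wts = np.exp(-dist / denom)
            if labels is not None:
                same = labels[r0:r1, c0:c1] == labels[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
                wts = wts * same
            num[r0:r1, c0:c1] += wts * arr[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
            den[r0:r1, c0:c1] += wts
    return num / den


def nlmeans_denoise(
    image: ImageLike,
    config: PatchConfig = PatchConfig(),
    *,
    labels: Optional[np.ndarray] = None,
) -> GrayImage:
    """Classic non-local-means filtering.

    ``labels`` (optional per-pixel cluster map of the image's shape)
    restricts each pixel's candidates to its own cluster — the coupling
    used by the K-means-guided pipeline.
    """
    arr = as_pixels(image)
    if labels is not None and labels.shape != arr.shape:
        raise ValueError("labels must have the image's shape")
    h = resolve_h(arr, config)
    out = _denoise_engine(arr, config, h, use_gradient=False, labels=labels)
    return GrayImage(out)


def nlmeans_gradient_denoise(
    image: ImageLike,
    config: PatchConfig = PatchConfig(),
    *,
    labels: Optional[np.ndarray] = None,
) -> GrayImage:
    """Gradient-augmented non-local-means filtering."""
    arr = as_pixels(image)
    if labels is not None and labels.shape != arr.shape:
        raise ValueError("labels must have the image's shape")
    h = resolve_h(arr, config)
    out = _denoise_engine(arr, config, h, use_gradient=True, labels=labels)
    return GrayImage(out)


def naive_oracle_denoise(
    image: ImageLike, config: PatchConfig = PatchConfig()
) -> GrayImage:
    """Literal whole-image evaluation of the weighted-average equations.

    Loops over every pixel pair, building each weight from
    ``patch_distance`` (times the gradient patch distance when
    ``config.use_gradient``), normalizing, and averaging.  Quadratic in
    the pixel count; inputs larger than 32x32 are refused.
    """
    arr = as_pixels(image)
    hgt, wid = arr.shape
    if hgt > ORACLE_MAX_SIDE or wid > ORACLE_MAX_SIDE:
        raise ValueError(
            f"oracle input limited to {ORACLE_MAX_SIDE}x{ORACLE_MAX_SIDE}, "
            f"got {hgt}x{wid}"
        )
    h = resolve_h(arr, config)
    denom = (config.a * h) ** 2
    grad = gradient_magnitude(arr) if config.use_gradient else None

    out = np.empty_like(arr)
    for iy in range(hgt):
        for ix in range(wid):
            weights = np.empty((hgt, wid))
            for jy in range(hgt):
                for jx in range(wid):
                    d = patch_distance(arr, (iy, ix), (jy, jx), config)
                    if config.use_gradient:
                        d *= patch_distance(grad, (iy, ix), (jy, jx), config)
                    weights[jy, jx] = np.exp(-d / denom)
            out[iy, ix] = np.sum(weights * arr) / np.sum(weights)
    return GrayImage(out)


def weight_field(
    image: ImageLike,
    i: tuple[int, int],
    config: PatchConfig,
    *,
    labels: Optional[np.ndarray] = None,
) -> WeightField:
    """Normalized candidate weights of target pixel ``i``.

    Candidates are the in-image pixels within the search window (all
    pixels under the whole-image sentinel), optionally restricted to
    ``i``'s cluster.  The weights sum to 1 by construction; the
    pre-normalization sum K(i) is reported alongside.
    """
    arr = as_pixels(image)
    hgt, wid = arr.shape
    iy, ix = i
    if not (0 <= iy < hgt and 0 <= ix < wid):
        raise ValueError(f"pixel {i} outside image {arr.shape}")
    r = config.patch_radius
    kern = _patch_kernel(config)
    h = resolve_h(arr, config)
    denom = (config.a * h) ** 2

    if config.search_radius is None:
        r0, r1, c0, c1 = 0, hgt, 0, wid
    else:
        s = config.search_radius
        r0, r1 = max(0, iy - s), min(hgt, iy + s + 1)
        c0, c1 = max(0, ix - s), min(wid, ix + s + 1)

    def _field_distance(field: np.ndarray) -> np.ndarray:
        padded = np.pad(field, r, mode="symmetric")
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, (2 * r + 1, 2 * r + 1)
        )
        diff = windows[r0:r1, c0:c1] - windows[iy, ix]
        return np.einsum("abkl,kl->ab", diff**2, kern)

    dist = _field_distance(arr)
    if config.use_gradient:
        dist = dist * _field_distance(gradient_magnitude(arr))
    raw = np.exp(-dist / denom)
    if labels is not None:
        raw = raw * (labels[r0:r1, c0:c1] == labels[iy, ix])

    rows, cols = np.mgrid[r0:r1, c0:c1]
    cand = np.stack([rows.ravel(), cols.ravel()], axis=1)
    raw = raw.ravel()
    normalizer = float(raw.sum())
    return WeightField(
        pixel=(iy, ix),
        candidates=cand,
        weights=raw / normalizer,
        normalizer=normalizer,
    )
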