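"""Per-pixel K-means clustering used to guide the non-local search.

Pixels are clustered on a two-component feature vector, the local patch
mean and patch standard deviation, which separates tissue classes under
signal-dependent speckle better than raw intensity.  The algorithm is the
classic Lloyd iteration: random distinct pixels initialize the centers,
each pixel is assigned to its nearest center (ties to the lowest cluster
index), centers are recomputed as member means, and iteration stops when
the centers stop moving (exact equality, with a 1e-12 absolute-tolerance
fallback for float arithmetic) or a cap is hit.  A cluster emptied by
reassignment is re-seeded to the point farthest from its nearest center,
so K live clusters are an invariant of the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial.distance import cdist

from .image import ImageLike, as_pixels

__all__ = [
    "PixelFeatures",
    "ClusterAssignment",
    "pixel_features",
    "init_centers",
    "assign_step",
    "update_step",
    "kmeans_run",
]

_CENTER_ATOL = 1e-12


@dataclass(frozen=True)
class PixelFeatures:
    """Per-pixel (patch mean, patch std) feature fields of one image."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std fields must share a shape")
        if np.any(self.std < 0):
            raise ValueError("patch std must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean.shape  # type: ignore[return-value]

    def as_matrix(self) -> np.ndarray:
        """Flatten to an (n_pixels, 2) observation matrix."""
        return np.stack([self.mean.ravel(), self.std.ravel()], axis=1)


FeatureLike = Union[PixelFeatures, np.ndarray]


def _as_matrix(features: FeatureLike) -> tuple[np.ndarray, Optional[tuple[int, int]]]:
    """Observation matrix plus the spatial shape to restore labels to.

    Accepts ``PixelFeatures``, a 2-D single-feature field (H, W), or an
    already flat (n, f) matrix (returned with no spatial shape).
    """
    if isinstance(features, PixelFeatures):
        return features.as_matrix(), features.shape
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim == 2:
        return arr.reshape(-1, 1), arr.shape
    raise ValueError("features must be PixelFeatures or a 2-D field")


@dataclass(frozen=True)
class ClusterAssignment:
    """Result of one K-means run.

    ``labels`` carries one cluster index per pixel (spatial shape when the
    input had one); ``objective_trace`` records the within-cluster sum of
    squares after every assignment step and is non-increasing.
    """

    labels: np.ndarray
    centers: np.ndarray
    iterations: int
    objective_trace: np.ndarray
    converged: bool

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centers": self.centers.tolist(),
            "iterations": self.iterations,
            "objective_trace": self.objective_trace.tolist(),
            "converged": self.converged,
        }


def pixel_features(image: ImageLike, patch_radius: int = 2) -> PixelFeatures:
    """Patch mean and std per pixel, with symmetric border padding."""
    if patch_radius < 1:
        raise ValueError("patch_radius must be >= 1")
    arr = as_pixels(image)
    size = 2 * patch_radius + 1
    # ndimage 'reflect' == numpy 'symmetric' (edge value repeated)
    mean = uniform_filter(arr, size=size, mode="reflect")
    mean_sq = uniform_filter(arr**2, size=size, mode="reflect")
    var = np.maximum(mean_sq - mean**2, 0.0)
    return PixelFeatures(mean=mean, std=np.sqrt(var))


def init_centers(features: FeatureLike, k: int, seed: int = 0) -> np.ndarray:
    """Feature vectors of ``k`` distinct pixels drawn uniformly at random."""
    x, _ = _as_matrix(features)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return x[idx].copy()


def _assign(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # np.argmin returns the first minimum, which is the tie rule
    return np.argmin(cdist(x, centers, metric="sqeuclidean"), axis=1)


def assign_step(features: FeatureLike, centers: np.ndarray) -> np.ndarray:
    """Label each pixel with its nearest center (ties: lowest index)."""
    x, shape = _as_matrix(features)
    centers = np.atleast_2d(centers)
    if centers.shape[0] < 1:
        raise ValueError("centers must be non-empty")
    labels = _assign(x, centers)
    return labels.reshape(shape) if shape is not None else labels


def _update(x: np.ndarray, flat: np.ndarray, centers: np.ndarray) -> np.ndarray:
    k = centers.shape[0]
    new = centers.astype(np.float64).copy()
    empty = []
    for j in range(k):
        members = flat == j
        if members.any():
            new[j] = x[members].mean(axis=0)
        else:
            empty.append(j)
    # re-seed against live centers only: stale positions of still-empty
    # clusters must not count as a "nearest center"
    live = [j for j in range(k) if j not in empty]
    for j in empty:
        if not live:  # pathological: every cluster empty
            live = [j]
            continue
        d = cdist(x, new[live], metric="sqeuclidean").min(axis=1)
        new[j] = x[int(np.argmax(d))]
        live.append(j)
    return new


def update_step(
    features: FeatureLike,
    labels: np.ndarray,
    centers: np.ndarray,
) -> np.ndarray:
    """Recompute each center as the mean of its members.

    ``centers`` supplies the cluster count and the previous positions; a
    cluster with no members is re-seeded to the observation farthest from
    its nearest (already updated) center, processed in index order.
    """
    x, _ = _as_matrix(features)
    return _update(x, np.asarray(labels).ravel(), np.atleast_2d(centers))


def _wcss(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(np.sum((x - centers[labels]) ** 2))


def kmeans_run(
    features: FeatureLike,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Full Lloyd iteration until the centers stop moving.

    Deterministic given (features, k, seed).  Exhausting ``max_iter``
    sets ``converged=False`` rather than raising.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    x, shape = _as_matrix(features)
    centers = init_centers(features, k, seed)
    trace = []
    labels = np.zeros(x.shape[0], dtype=np.intp)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        labels = _assign(x, centers)
        trace.append(_wcss(x, labels, centers))
        new_centers = _update(x, labels, centers)
        if np.allclose(new_centers, centers, rtol=0.0, atol=_CENTER_ATOL):
            centers = new_centers
            converged = True
            break
        centers = new_centers
    return ClusterAssignment(
        labels=labels.reshape(shape) if shape is not None else labels,
        centers=centers,
        iterations=iterations,
        objective_trace=np.asarray(trace),
        converged=converged,
    )
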