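"""Region-based segmentation: K-means over per-pixel features + ROI mask.

Pixels are clustered by squared Euclidean distance in a colour feature
space (RGB, or intensity for grayscale inputs), optionally augmented with
the local mean of luminance over a 3x3 neighbourhood. The region of
interest is the union of all clusters except the background cluster,
identified as the cluster whose pixels most often touch the image border
(ties broken by lower mean luminance).

K-means is the plain Lloyd iteration with seeded initialization at k
distinct data points, a tolerance on the inertia improvement, and
empty-cluster repair by re-seeding at the point farthest from its
centroid. These rules are pinned here (rather than delegated to a library
implementation) so segmentations are bit-reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial.distance import cdist

from .gabor import to_luminance


class DegenerateClusteringError(ValueError):
    """Raised when k exceeds the number of distinct feature points."""


@dataclass
class SegmentationResult:
    label_map: np.ndarray  # H x W int, values in {0..k-1}
    centroids: np.ndarray  # k x d
    inertia: float
    roi_mask: np.ndarray  # H x W bool


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-8,
    n_restarts: int = 1,
    record_trace: bool = False,
):
    """Lloyd K-means with squared Euclidean distance.

    Returns ``(centroids, assignments, inertia)`` — or with a fourth
    element, the per-iteration inertia trace, when ``record_trace`` is
    set. With ``n_restarts > 1`` the restart with the lowest inertia wins.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    if points.ndim == 1:
        points = points[:, None]  # n scalar observations
    if points.ndim != 2:
        raise ValueError("points must be a non-empty (n, d) array")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    n = points.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be in [1, n={n}]")
    distinct = np.unique(points, axis=0)
    if k > distinct.shape[0]:
        raise DegenerateClusteringError(
            f"degenerate clustering: k={k} exceeds {distinct.shape[0]} distinct points"
        )

    best = None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        result = _lloyd(points, distinct, k, rng, max_iter, tol)
        if best is None or result[2] < best[2]:
            best = result
    assert best is not None
    if record_trace:
        return best
    return best[:3]


def _lloyd(points, distinct, k, rng, max_iter, tol):
    n = points.shape[0]
    centroids = distinct[rng.choice(distinct.shape[0], size=k, replace=False)].copy()
    prev_inertia = np.inf
    trace = []
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(points, centroids, metric="sqeuclidean")
        assign = np.argmin(d2, axis=1)  # ties -> lower centroid index
        inertia = float(d2[np.arange(n), assign].sum())
        trace.append(inertia)
        for c in range(k):
            members = assign == c
            if members.any():
                centroids[c] = points[members].mean(axis=0)
            else:
                # re-seed the empty centroid at the point farthest from its own centroid
                worst = int(np.argmax(d2[np.arange(n), assign]))
                centroids[c] = points[worst]
        if prev_inertia - inertia < tol:
            break
        prev_inertia = inertia
    d2 = cdist(points, centroids, metric="sqeuclidean")
    assign = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(n), assign].sum())
    trace.append(inertia)
    return centroids, assign, inertia, trace


def equalize_hist(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Plain histogram equalization of a [0, 1] grayscale image."""
    image = np.asarray(image, dtype=float)
    hist, edges = np.histogram(image.ravel(), bins=n_bins, range=(0.0, 1.0))
    cdf = hist.cumsum().astype(float)
    if cdf[-1] == 0:
        return image.copy()
    cdf /= cdf[-1]
    return np.interp(image.ravel(), edges[:-1], cdf).reshape(image.shape)


def pixel_features(image: np.ndarray, use_local_mean: bool = False) -> np.ndarray:
    """Per-pixel feature rows: colour channels (+ 3x3 local-mean luminance)."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        feats = image[:, :, None]
    elif image.ndim == 3:
        feats = image
    else:
        raise ValueError(f"expected 2D or 3D image, got shape {image.shape}")
    h, w = feats.shape[:2]
    cols = [feats.reshape(h * w, -1)]
    if use_local_mean:
        lum = to_luminance(image) if image.ndim == 3 else image
        cols.append(uniform_filter(lum, size=3, mode="nearest").reshape(h * w, 1))
    return np.hstack(cols)


def select_roi(label_map: np.ndarray, image: np.ndarray) -> np.ndarray:
    """ROI = union of all clusters except the background cluster.

    Background is the cluster with the highest fraction of its pixels on
    the image border; ties break toward the cluster with lower mean
    luminance. If only one cluster is present the mask is empty (with a
    warning).
    """
    label_map = np.asarray(label_map)
    h, w = label_map.shape
    labels = np.unique(label_map)
    if labels.size == 1:
        warnings.warn("single-cluster segmentation: empty ROI", stacklevel=2)
        return np.zeros((h, w), dtype=bool)
    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    lum = to_luminance(image)
    scores = []
    for lab in labels:
        members = label_map == lab
        frac = border[members].mean()
        scores.append((frac, -float(lum[members].mean()), lab))
    background = max(scores)[2]
    return label_map != background


def segment_image(
    image: np.ndarray,
    k: int = 3,
    use_local_mean: bool = False,
    seed: int = 0,
    equalize: bool = False,
    n_restarts: int = 1,
) -> SegmentationResult:
    """Cluster pixels with K-means and extract the ROI mask."""
    if k < 2:
        raise ValueError("k must be >= 2")
    image = np.asarray(image, dtype=float)
    work = image
    if equalize:
        if image.ndim == 3:
            work = np.stack([equalize_hist(image[:, :, c]) for c in range(image.shape[2])], axis=2)
        else:
            work = equalize_hist(image)
    feats = pixel_features(work, use_local_mean=use_local_mean)
    h, w = image.shape[:2]
    centroids, assign, inertia = kmeans(feats, k, seed=seed, n_restarts=n_restarts)
    label_map = assign.reshape(h, w)
    roi = select_roi(label_map, image)
    return SegmentationResult(label_map=label_map, centroids=centroids, inertia=inertia, roi_mask=roi)


def apply_roi(image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Zero out background pixels before feature extraction."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if image.ndim == 3:
        return image * mask[:, :, None]
    return image * mask
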