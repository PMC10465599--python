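"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (quadruple loops, exhaustive
enumeration) and are written against the mathematical definitions, not
against the package's optimized implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from leafdx import data


def brute_convolve2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True convolution (kernel flipped), zero padding, same-size output."""
    h, w = image.shape
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((h, w), dtype=np.result_type(image, kernel))
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    yy = y - (i - ph)
                    xx = x - (j - pw)
                    if 0 <= yy < h and 0 <= xx < w:
                        acc += image[yy, xx] * kernel[i, j]
            out[y, x] = acc
    return out


def brute_conv_layer(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray, padding: int) -> np.ndarray:
    """Cross-correlation conv layer, stride 1, explicit loops."""
    n, c, h, w = x.shape
    o, _, kh, kw = kernels.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho, wo = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1
    out = np.zeros((n, o, ho, wo))
    for b in range(n):
        for p in range(o):
            for y in range(ho):
                for xx in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                acc += xp[b, ci, y + i, xx + j] * kernels[p, ci, i, j]
                    out[b, p, y, xx] = acc + biases[p]
    return out


def best_two_partition_inertia(points: np.ndarray) -> float:
    """Exhaustive minimum within-cluster sum of squares over all 2-partitions."""
    n = points.shape[0]
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n):
        if 0 < sum(bits) < n:
            total = 0.0
            for g in (0, 1):
                members = points[np.array(bits) == g]
                total += float(((members - members.mean(axis=0)) ** 2).sum())
            best = min(best, total)
    return best


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 images, 10 per class, 32x32, low noise."""
    spec = data.DatasetSpec(
        class_counts={name: 10 for name in data.CLASS_NAMES},
        image_size=(32, 32),
        noise_sigma=0.02,
        seed=7,
    )
    images, manifest = data.generate_dataset(spec)
    return spec, images, manifest
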