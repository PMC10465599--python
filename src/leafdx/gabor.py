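"""Gabor-filter pre-processing.

The 2D Gabor elementary function used here is an isotropic Gaussian
envelope (space constant ``omega`` along both axes) modulating a complex
plane wave with spatial frequencies ``(u, v)`` in cycles/pixel:

    g(x, y) = 1/(2*pi*omega^2) * exp(-(x^2 + y^2)/(2*omega^2))
                                * exp(j*2*pi*(u*x + v*y))

Pre-processing convolves the luminance image with this kernel in the
spatial domain (true convolution, zero padding, same-size output) and, by
default, keeps the modulus of the complex response rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d as _scipy_convolve2d

#: Rec. 601 luma weights used to collapse RGB to luminance.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GaborParams:
    """Gabor kernel parameters.

    omega : isotropic Gaussian space constant, pixels (> 0)
    u, v  : horizontal / vertical spatial frequency, cycles per pixel
    half_size : kernel covers integer offsets x, y in [-half_size, half_size]
    """

    omega: float = 2.0
    u: float = 0.125
    v: float = 0.0
    half_size: int = 12

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.half_size < 1:
            raise ValueError("half_size must be >= 1")


@dataclass(frozen=True)
class ComplexKernel:
    """A sampled complex Gabor kernel plus the parameters that built it."""

    values: np.ndarray  # (2*half_size+1, 2*half_size+1) complex
    params: GaborParams

    def at(self, x: int, y: int) -> complex:
        """Kernel value at integer offset (x horizontal, y vertical)."""
        h = self.params.half_size
        return complex(self.values[y + h, x + h])


def gabor_kernel(params: GaborParams) -> ComplexKernel:
    """Sample g(x, y) at integer offsets on the (2h+1)^2 grid.

    Rows index the vertical offset y, columns the horizontal offset x,
    both running from -half_size to +half_size.
    """
    h = params.half_size
    offs = np.arange(-h, h + 1)
    yy = offs[:, None]
    xx = offs[None, :]
    envelope = np.exp(-(xx**2 + yy**2) / (2.0 * params.omega**2)) / (
        2.0 * np.pi * params.omega**2
    )
    phase = np.exp(2j * np.pi * (params.u * xx + params.v * yy))
    return ComplexKernel(values=envelope * phase, params=params)


def convolve2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2D convolution (kernel flipped), zero padding, same-size output.

    The kernel must have odd side lengths so the output is centred.
    """
    image = np.asarray(image)
    kernel = np.asarray(kernel)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    if kernel.ndim != 2 or kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError("kernel must be 2D with odd side lengths")
    return _scipy_convolve2d(image, kernel, mode="same", boundary="fill", fillvalue=0)


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Collapse an H x W x 3 image to luminance; pass 2D images through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ LUMA_WEIGHTS
    raise ValueError(f"expected 2D or HxWx3 image, got shape {image.shape}")


def gabor_filter(
    image: np.ndarray,
    params: GaborParams = GaborParams(),
    response: str = "modulus",
) -> np.ndarray:
    """Filter an image with the Gabor kernel and return a real [0, 1] map.

    ``response`` selects how the complex response becomes real:

    * ``modulus`` (default) - magnitude, rescaled by its maximum,
    * ``real`` / ``imag``  - the component, min-max rescaled to [0, 1].

    A uniformly zero response maps to an all-zero output.
    """
    from .data import LabeledImage  # local import to avoid a cycle

    if isinstance(image, LabeledImage):
        image = image.pixels
    lum = to_luminance(image)
    resp = convolve2d(lum, gabor_kernel(params).values)
    if response == "modulus":
        out = np.abs(resp)
        peak = out.max()
        return out / peak if peak > 0 else np.zeros_like(out)
    if response in ("real", "imag"):
        out = resp.real if response == "real" else resp.imag
        lo, hi = out.min(), out.max()
        return (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    raise ValueError(f"unknown response mode: {response!r}")
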