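"""2-D convolution with configurable border handling and arithmetic mode.

The convolution is the plain direct form

    out(p) = sum_t k(t) * img(p - t + center)

computed as an explicit tap loop so that float and fixed-point modes share one
code path.  In ``fixed`` mode the coefficients are first snapped onto the
Q-format lattice and the multiply-accumulate is carried exactly on that
integer lattice (a widening accumulator with no intermediate rounding), after
which the result is divided back by 2^frac_bits.  All products and partial
sums stay far below 2^53, so float64 arithmetic on the integer lattice is
exact.

8-bit conversion follows the hardware contract: smoothing outputs are clamped
to [0, 255] and truncated toward zero; gLoG response maps are affinely
min-max rescaled to [0, 255] before truncation (rescaling preserves the
intensity ordering that regional-maxima extraction depends on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, ParameterError
from .kernels import (
    Q2_14,
    FixedPointFormat,
    Kernel2D,
    KernelBank,
    make_gaussian_kernel,
    quantized_ints,
)

__all__ = [
    "ConvolutionConfig",
    "convolve2d",
    "to_uint8",
    "gaussian_smooth",
    "glog_response_maps",
]

_BORDER_MODES = {"replicate": "edge", "zero": "constant", "reflect": "reflect"}
_ARITHMETIC = ("float", "fixed")


@dataclass(frozen=True)
class ConvolutionConfig:
    """Border handling and arithmetic mode for pipeline convolutions."""

    border_mode: str = "replicate"
    arithmetic: str = "float"
    fixed_format: FixedPointFormat = field(default=Q2_14)

    def __post_init__(self) -> None:
        if self.border_mode not in _BORDER_MODES:
            raise ParameterError(
                f"border_mode must be one of {sorted(_BORDER_MODES)}, got {self.border_mode!r}"
            )
        if self.arithmetic not in _ARITHMETIC:
            raise ParameterError(
                f"arithmetic must be one of {_ARITHMETIC}, got {self.arithmetic!r}"
            )


def _pad(img: np.ndarray, size: tuple[int, int], center: tuple[int, int], mode: str) -> np.ndarray:
    sr, sc = size
    cr, cc = center
    pads = ((sr - 1 - cr, cr), (sc - 1 - cc, cc))
    if mode == "reflect":
        if max(pads[0]) >= img.shape[0] or max(pads[1]) >= img.shape[1]:
            raise DimensionError(
                f"kernel {size} too large for reflect padding of image {img.shape}"
            )
    kwargs = {"constant_values": 0} if mode == "constant" else {}
    return np.pad(img, pads, mode=mode, **kwargs)


def convolve2d(
    img: np.ndarray, k: Kernel2D, cfg: ConvolutionConfig = ConvolutionConfig()
) -> np.ndarray:
    """Full-size 2-D convolution of an 8-bit image with a kernel.

    Returns a real-valued float64 image of the same shape as ``img``.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {img.shape}")
    h, w = img.shape
    sr, sc = k.size

    if cfg.arithmetic == "fixed":
        weights = quantized_ints(k, cfg.fixed_format).astype(np.float64)
        scale = float(1 << cfg.fixed_format.frac_bits)
    else:
        weights = k.weights
        scale = 1.0

    padded = _pad(img.astype(np.float64), k.size, k.center, _BORDER_MODES[cfg.border_mode])
    out = np.zeros((h, w), dtype=np.float64)
    # out(p) = sum_t k(t) * padded[p + (s-1) - t]; tap order fixed for determinism
    for ti in range(sr):
        for tj in range(sc):
            wgt = weights[ti, tj]
            if wgt == 0.0:
                continue
            out += wgt * padded[sr - 1 - ti : sr - 1 - ti + h, sc - 1 - tj : sc - 1 - tj + w]
    if scale != 1.0:
        out /= scale
    return out


def to_uint8(img: np.ndarray, rescale: bool = False) -> np.ndarray:
    """Convert a real-valued map to 8 bits as the hardware stores it.

    ``rescale=False`` (smoothing path): clamp to [0, 255] and truncate toward
    zero.  ``rescale=True`` (response-map path): min-max affine rescale onto
    [0, 255], then truncate; a constant map degenerates to all zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    if rescale:
        lo, hi = img.min(), img.max()
        if hi == lo:
            return np.zeros(img.shape, dtype=np.uint8)
        img = (img - lo) / (hi - lo) * 255.0
    return np.trunc(np.clip(img, 0.0, 255.0)).astype(np.uint8)


def gaussian_smooth(
    img: np.ndarray,
    size: int = 7,
    sigma: float = 1.0,
    cfg: ConvolutionConfig = ConvolutionConfig(),
) -> np.ndarray:
    """Gaussian lowpass: H = to_uint8(img * Gaussian(size, sigma))."""
    k = make_gaussian_kernel(size, sigma)
    return to_uint8(convolve2d(img, k, cfg))


def glog_response_maps(
    H: np.ndarray,
    bank: KernelBank,
    cfg: ConvolutionConfig = ConvolutionConfig(),
    negate: bool = False,
) -> list[np.ndarray]:
    """One 8-bit response map per bank filter, in order theta_0..theta_{n-1}, RS.

    ``negate=True`` flips the response sign before rescaling, so maxima land on
    bright blobs instead of dark ones (the raw Laplacian kernel has a negative
    centre tap and therefore peaks on dark blobs).
    """
    filters = bank.filters
    if not filters:
        raise ParameterError("empty kernel bank")
    maps = []
    for k in filters:
        resp = convolve2d(H, k, cfg)
        if negate:
            resp = -resp
        maps.append(to_uint8(resp, rescale=True))
    return maps
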