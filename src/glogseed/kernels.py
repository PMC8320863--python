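"""Gaussian smoothing kernel and the generalized-LoG (gLoG) filter bank.

A gLoG kernel is the Laplacian of an oriented anisotropic 2-D Gaussian

    G(x, y) = lam * exp(-(a x^2 + 2 b x y + c y^2))

with the standard quadratic-form parameterization in scale (sigma_x,
sigma_y) and orientation theta:

    a =  cos^2(theta) / (2 sigma_x^2) + sin^2(theta) / (2 sigma_y^2)
    b = -sin(2 theta) / (4 sigma_x^2) + sin(2 theta) / (4 sigma_y^2)
    c =  sin^2(theta) / (2 sigma_x^2) + cos^2(theta) / (2 sigma_y^2)

and lam = 1 / (2 pi sigma_x sigma_y) so the continuous G integrates to 1.
The Laplacian is evaluated in closed form,

    lap G = ((2 a x + 2 b y)^2 + (2 b x + 2 c y)^2 - 2 a - 2 c) * G,

sampled on a square grid, and shifted to exact zero mean so flat image
regions give zero response.  The bank sums kernels of a common orientation
over all anisotropic scale pairs (sigma_x > sigma_y), plus one rotationally
symmetric filter summed over the isotropic scales, matching blob-like nuclei
of elliptical and circular shape.

Fixed-point quantization mirrors the signed Q-format coefficient tables used
by streaming hardware implementations (default Q2.14: 16 bits, 14
fractional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .exceptions import ParameterError, QuantizationOverflowError

__all__ = [
    "Kernel2D",
    "FixedPointFormat",
    "Q2_14",
    "GLoGBankSpec",
    "KernelBank",
    "make_gaussian_kernel",
    "glog_kernel",
    "build_glog_filter_bank",
    "quantize_kernel",
    "scale_grid",
]


@dataclass(frozen=True)
class FixedPointFormat:
    """Signed fixed-point representation: ``total_bits`` with ``frac_bits`` fractional."""

    total_bits: int = 16
    frac_bits: int = 14
    signed: bool = True

    def __post_init__(self) -> None:
        if self.frac_bits >= self.total_bits:
            raise ParameterError("frac_bits must be smaller than total_bits")

    @property
    def resolution(self) -> float:
        return 2.0 ** -self.frac_bits

    @property
    def int_min(self) -> int:
        return -(2 ** (self.total_bits - 1)) if self.signed else 0

    @property
    def int_max(self) -> int:
        return 2 ** (self.total_bits - 1) - 1 if self.signed else 2 ** self.total_bits - 1


#: The paper-printed default coefficient format: 16-bit, 14 fractional bits.
Q2_14 = FixedPointFormat(16, 14, True)


@dataclass
class Kernel2D:
    """A 2-D filter: tap weights plus the (row, col) tap treated as the origin."""

    weights: np.ndarray
    center: tuple[int, int]
    name: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ParameterError("kernel weights must be 2-D")

    @property
    def size(self) -> tuple[int, int]:
        return self.weights.shape


def _grid(size: int, center: int) -> tuple[np.ndarray, np.ndarray]:
    """Sampling coordinates: x = col - center_col, y = row - center_row."""
    rows = np.arange(size) - center
    y, x = np.meshgrid(rows, rows, indexing="ij")
    return x.astype(np.float64), y.astype(np.float64)


def default_center(size: int) -> tuple[int, int]:
    """Origin tap: for even sizes the lower-right of the four central taps."""
    return (size // 2, size // 2)


def make_gaussian_kernel(size: int, sigma: float) -> Kernel2D:
    """Isotropic Gaussian smoothing kernel, normalized to sum to 1.

    Parameters
    ----------
    size : side length in pixels (odd or even).
    sigma : standard deviation in pixels; must be positive.
    """
    if size < 1:
        raise ParameterError(f"kernel size must be >= 1, got {size}")
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    c = size // 2
    x, y = _grid(size, c)
    w = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    w /= w.sum()
    return Kernel2D(w, (c, c), name=f"gauss{size}x{size}_s{sigma:g}")


def glog_kernel(sigma_x: float, sigma_y: float, theta: float, size: int = 25) -> Kernel2D:
    """One zero-mean gLoG kernel at scale (sigma_x, sigma_y) and orientation theta.

    The bank convention is sigma_x >= sigma_y > 0 (sigma_x = sigma_y gives the
    rotationally symmetric case, independent of theta).
    """
    if size < 3:
        raise ParameterError(f"gLoG kernel size must be >= 3, got {size}")
    if sigma_y <= 0:
        raise ParameterError("sigma_y must be positive")
    if sigma_x < sigma_y:
        raise ParameterError(
            f"bank convention requires sigma_x >= sigma_y, got {sigma_x} < {sigma_y}"
        )
    sx2 = 2.0 * sigma_x * sigma_x
    sy2 = 2.0 * sigma_y * sigma_y
    ct, st = math.cos(theta), math.sin(theta)
    a = ct * ct / sx2 + st * st / sy2
    b = -math.sin(2.0 * theta) / (2.0 * sx2) + math.sin(2.0 * theta) / (2.0 * sy2)
    c = st * st / sx2 + ct * ct / sy2
    lam = 1.0 / (2.0 * math.pi * sigma_x * sigma_y)

    ctr = size // 2
    x, y = _grid(size, ctr)
    g = lam * np.exp(-(a * x * x + 2.0 * b * x * y + c * y * y))
    gx = 2.0 * a * x + 2.0 * b * y
    gy = 2.0 * b * x + 2.0 * c * y
    lap = (gx * gx + gy * gy - 2.0 * a - 2.0 * c) * g
    lap -= lap.mean()  # exact zero mean on the sampled grid
    return Kernel2D(lap, (ctr, ctr), name=f"glog_sx{sigma_x:g}_sy{sigma_y:g}_t{theta:.4f}")


@dataclass(frozen=True)
class GLoGBankSpec:
    """Scale/orientation grid of the gLoG bank (defaults match typical nuclei of 6-12 px)."""

    sigma_min: float = 6.0
    sigma_max: float = 12.0
    sigma_step: float = 0.5
    n_orientations: int = 9
    kernel_size: int = 25

    def __post_init__(self) -> None:
        if not self.sigma_min < self.sigma_max:
            raise ParameterError("sigma_min must be < sigma_max")
        if self.sigma_step <= 0:
            raise ParameterError("sigma_step must be positive")
        if self.n_orientations < 1:
            raise ParameterError("n_orientations must be >= 1")
        if self.kernel_size < 3:
            raise ParameterError("kernel_size must be >= 3")


def scale_grid(spec: GLoGBankSpec) -> np.ndarray:
    """The discrete scale set {sigma_min, sigma_min+step, ..., sigma_max}."""
    n = int(round((spec.sigma_max - spec.sigma_min) / spec.sigma_step)) + 1
    return spec.sigma_min + spec.sigma_step * np.arange(n)


@dataclass
class KernelBank:
    """Nine oriented summed gLoG filters plus one rotationally symmetric (RS) filter."""

    oriented: list[Kernel2D] = field(default_factory=list)
    symmetric: Kernel2D | None = None

    @property
    def filters(self) -> list[Kernel2D]:
        """All filters in response-map order: theta_0 .. theta_{n-1}, then RS."""
        out = list(self.oriented)
        if self.symmetric is not None:
            out.append(self.symmetric)
        return out

    def __len__(self) -> int:
        return len(self.filters)


@lru_cache(maxsize=8)
def build_glog_filter_bank(spec: GLoGBankSpec = GLoGBankSpec()) -> KernelBank:
    """Build the filter bank: one summed filter per orientation plus the RS filter.

    Each oriented filter is the elementwise sum of gLoG kernels at that
    orientation over all scale pairs with sigma_x > sigma_y drawn from the
    scale grid; the RS filter sums the isotropic (sigma_x = sigma_y) kernels.
    """
    scales = scale_grid(spec)
    size = spec.kernel_size
    ctr = default_center(size)
    pairs = [(sx, sy) for i, sx in enumerate(scales) for sy in scales[:i]]

    oriented = []
    for n in range(spec.n_orientations):
        theta = n * math.pi / spec.n_orientations
        acc = np.zeros((size, size))
        for sx, sy in pairs:
            acc += glog_kernel(float(sx), float(sy), theta, size).weights
        oriented.append(Kernel2D(acc, ctr, name=f"theta_{n}"))

    acc = np.zeros((size, size))
    for s in scales:
        acc += glog_kernel(float(s), float(s), 0.0, size).weights
    symmetric = Kernel2D(acc, ctr, name="RS")
    return KernelBank(oriented=oriented, symmetric=symmetric)


def quantize_kernel(k: Kernel2D, fmt: FixedPointFormat = Q2_14) -> Kernel2D:
    """Snap every weight onto the fixed-point lattice: round(w * 2^frac) / 2^frac.

    Raises
    ------
    QuantizationOverflowError
        If any weight's integer representation falls outside the signed range.
    """
    q = np.rint(k.weights * (1 << fmt.frac_bits))
    bad = (q < fmt.int_min) | (q > fmt.int_max)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise QuantizationOverflowError(
            f"weight {k.weights[r, c]!r} at tap ({r}, {c}) overflows "
            f"Q{fmt.total_bits - 1 - fmt.frac_bits}.{fmt.frac_bits}"
        )
    return Kernel2D(q / (1 << fmt.frac_bits), k.center, name=k.name + "_q")


def quantized_ints(k: Kernel2D, fmt: FixedPointFormat = Q2_14) -> np.ndarray:
    """Integer lattice representation of the quantized weights (for exact arithmetic)."""
    q = quantize_kernel(k, fmt)
    return np.rint(q.weights * (1 << fmt.frac_bits)).astype(np.int64)
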