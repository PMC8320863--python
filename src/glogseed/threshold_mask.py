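"""Otsu thresholding of the smoothed image, AND-masking, candidate pooling.

The smoothed image H is binarized into a nuclei mask T with a global
threshold tau (Otsu's between-class-variance maximizer over the 256-bin
histogram, or a user-pinned value).  Each regional-maxima map R_i is ANDed
with T to suppress false maxima outside nuclei, and the surviving pixels from
all maps are pooled (deduplicated) into the seed-candidate set S.

Polarity: the printed rule marks H < tau as nuclei (dark nuclei on the plain
red channel); with ``polarity="above"`` the mask keeps H >= tau instead
(bright nuclei after complementing the input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateHistogramError, DimensionError, ParameterError

__all__ = [
    "ThresholdConfig",
    "otsu_threshold",
    "threshold_image",
    "mask_response",
    "collect_candidates",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold value (0..255 or "auto" for Otsu) and comparison polarity."""

    tau: int | str = "auto"
    polarity: str = "below"

    def __post_init__(self) -> None:
        if isinstance(self.tau, str):
            if self.tau != "auto":
                raise ParameterError(f"tau must be an intensity or 'auto', got {self.tau!r}")
        elif not 0 <= int(self.tau) <= 255:
            raise ParameterError(f"explicit tau must lie in [0, 255], got {self.tau}")
        if self.polarity not in ("below", "above"):
            raise ParameterError(f"polarity must be 'below' or 'above', got {self.polarity!r}")


def otsu_threshold(H: np.ndarray) -> int:
    """Otsu's threshold: maximize between-class variance w0*w1*(mu0-mu1)^2.

    Classes for candidate tau are {v < tau} and {v >= tau}, matching the
    mask rule.  Ties are broken toward the smallest maximizing tau.

    Raises
    ------
    DegenerateHistogramError
        If the image has fewer than two distinct values.
    """
    H = np.asarray(H)
    hist = np.bincount(H.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("Otsu requires at least two distinct intensities")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # for tau = 1..255: class 0 holds bins [0, tau), class 1 holds [tau, 256)
    w0 = np.cumsum(hist)[:-1] / total            # weight of class 0 at tau = k+1
    s0 = np.cumsum(hist * levels)[:-1] / total   # first moment of class 0
    mu = s0[-1] + hist[255] * 255.0 / total      # global mean
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(255)
    between[valid] = (mu * w0[valid] - s0[valid]) ** 2 / (w0[valid] * w1[valid])
    return int(np.argmax(between)) + 1


def threshold_image(H: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Binary nuclei mask T: H < tau (polarity "below") or H >= tau ("above")."""
    H = np.asarray(H)
    tau = otsu_threshold(H) if cfg.tau == "auto" else int(cfg.tau)
    if cfg.polarity == "below":
        return (H < tau).astype(np.uint8)
    return (H >= tau).astype(np.uint8)


def mask_response(R: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Elementwise logical AND of a regional-maxima map with the nuclei mask."""
    R = np.asarray(R)
    T = np.asarray(T)
    if R.shape != T.shape:
        raise DimensionError(f"response map shape {R.shape} != mask shape {T.shape}")
    return ((R != 0) & (T != 0)).astype(np.uint8)


def collect_candidates(masked_maps: list[np.ndarray]) -> np.ndarray:
    """Union of set pixels across all masked maps, as a deduplicated, row-major
    sorted (n, 2) integer array of (row, col) coordinates."""
    if not masked_maps:
        return np.empty((0, 2), dtype=np.int64)
    shape = np.asarray(masked_maps[0]).shape
    acc = np.zeros(shape, dtype=bool)
    for m in masked_maps:
        m = np.asarray(m)
        if m.shape != shape:
            raise DimensionError("masked maps must share dimensions")
        acc |= m != 0
    return np.argwhere(acc).astype(np.int64)
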