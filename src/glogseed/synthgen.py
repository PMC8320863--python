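"""Synthetic histology-like images with known nuclei centers, plus scoring.

Nuclei are rendered as anisotropic Gaussian-profile elliptical blobs on a
contrasting background with additive Gaussian noise — the appearance class
the gLoG bank targets.  The default rendering is dark nuclei on a bright
background (as in the plain red channel of an H&E image); ``bright_on_dark``
flips the contrast to exercise the complemented-input path.

The blob profile along each principal axis is exp(-u^2 / (2 sigma^2)) with
sigma = semi-axis / 2, so the nominal radius sits at the 2-sigma falloff of
the profile.

Detections are scored against ground truth by greedy one-to-one matching in
order of increasing distance, a detection counting as a true positive when it
lies within a tolerance of an unmatched truth center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, PlacementError

__all__ = ["SynthConfig", "GroundTruth", "generate_image", "evaluate_detection"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give well-separated mid-contrast nuclei."""

    image_size: int = 256
    n_nuclei: int = 15
    radius_range: tuple[float, float] = (6.0, 12.0)
    eccentricity_range: tuple[float, float] = (1.0, 1.8)
    background: int = 200
    nucleus_intensity: int = 100
    noise_sigma: float = 3.0
    min_center_separation: float = 30.0
    rng_seed: int = 0
    bright_on_dark: bool = False

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ParameterError("radius_range must be positive and ordered")
        if self.min_center_separation < 0:
            raise ParameterError("min_center_separation must be >= 0")
        if not (0 <= self.background <= 255 and 0 <= self.nucleus_intensity <= 255):
            raise ParameterError("intensity levels must lie in [0, 255]")
        margin = self.radius_range[1] + 4
        if self.image_size <= 2 * margin and self.n_nuclei > 0:
            raise ParameterError("image too small to fit nuclei inside the margin")


@dataclass
class GroundTruth:
    """True nucleus geometry: centers (n, 2), semi-axes (n, 2), orientations (n,)."""

    centers: np.ndarray
    axes: np.ndarray
    thetas: np.ndarray


def _place_centers(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    margin = cfg.radius_range[1] + 4
    lo, hi = margin, cfg.image_size - margin
    centers: list[np.ndarray] = []
    min2 = cfg.min_center_separation ** 2
    for _ in range(20000):
        if len(centers) == cfg.n_nuclei:
            break
        cand = rng.uniform(lo, hi, size=2)
        if all(((cand - c) ** 2).sum() >= min2 for c in centers):
            centers.append(cand)
    else:
        raise PlacementError(
            f"could not place {cfg.n_nuclei} nuclei at separation "
            f">= {cfg.min_center_separation} in a {cfg.image_size}px image"
        )
    return np.asarray(centers).reshape(-1, 2)


def generate_image(cfg: SynthConfig = SynthConfig()) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic image and its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(cfg.rng_seed)
    centers = _place_centers(cfg, rng)
    n = len(centers)
    rmin, rmax = cfg.radius_range
    minor = rng.uniform(rmin, rmax, size=n)
    ecc = rng.uniform(*cfg.eccentricity_range, size=n)
    major = np.minimum(minor * ecc, rmax)
    thetas = rng.uniform(0.0, math.pi, size=n)

    bg = float(cfg.background)
    amp = float(cfg.nucleus_intensity) - bg
    if cfg.bright_on_dark:
        bg = float(cfg.nucleus_intensity)
        amp = float(cfg.background) - bg

    size = cfg.image_size
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    field_img = np.full((size, size), bg)
    for (cr, cc), a, b, th in zip(centers, major, minor, thetas):
        dy = rows - cr
        dx = cols - cc
        # rotate into the blob frame; profile sigma = semi-axis / 2
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        sa, sb = a / 2.0, b / 2.0
        field_img += amp * np.exp(-(u * u / (2 * sa * sa) + v * v / (2 * sb * sb)))
    if cfg.noise_sigma > 0:
        field_img += rng.normal(0.0, cfg.noise_sigma, size=field_img.shape)
    img = np.rint(np.clip(field_img, 0, 255)).astype(np.uint8)
    return img, GroundTruth(centers=centers, axes=np.column_stack([major, minor]), thetas=thetas)


def evaluate_detection(
    detected: np.ndarray, truth: GroundTruth | np.ndarray, tol: float
) -> tuple[float, float, float]:
    """Precision, recall and F1 of detections vs ground-truth centers.

    Greedy one-to-one matching by increasing distance; a detection within
    ``tol`` of an unmatched truth center is a true positive.  Conventions for
    empty sets: precision of empty detections is 1 if the truth is empty,
    else 0; recall over an empty truth is 1.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    tru = truth.centers if isinstance(truth, GroundTruth) else np.asarray(truth, dtype=float)
    tru = tru.reshape(-1, 2)
    nd, nt = len(det), len(tru)
    if nd == 0 and nt == 0:
        return 1.0, 1.0, 1.0
    if nd == 0:
        return 0.0, 0.0, 0.0
    if nt == 0:
        return 0.0, 1.0, 0.0

    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    pairs = [(d[i, j], i, j) for i in range(nd) for j in range(nt) if d[i, j] <= tol]
    pairs.sort()
    used_d = np.zeros(nd, dtype=bool)
    used_t = np.zeros(nt, dtype=bool)
    tp = 0
    for _, i, j in pairs:
        if not used_d[i] and not used_t[j]:
            used_d[i] = used_t[j] = True
            tp += 1
    precision = tp / nd
    recall = tp / nt
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1
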