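"""Regional maxima by hybrid grayscale reconstruction.

A regional maximum is an 8-connected plateau of constant value whose external
boundary pixels are all strictly lower.  They are isolated by morphological
reconstruction by dilation: build the marker J = max(I - 1, 0), reconstruct J
under the mask I, and mark pixels where I - J' equals exactly 1.

The reconstruction uses the sequential hybrid algorithm: one raster scan, one
anti-raster scan that also seeds a FIFO queue, then queue-driven propagation
of the remaining changes.  It is equivalent to (but far faster than) naively
iterating pointwise min(dilate(J), I) to a fixed point; the naive iteration is
kept as an independent oracle.

Connectivity is 8-connected throughout; neighbors outside the image are
skipped, so a border plateau with no lower in-image neighbor still counts as
a maximum.  Note that pixels with I = 0 have J = J' = 0 and thus never pass
the "difference equals 1" test: an all-zero image yields no maxima.
"""

from __future__ import annotations

import random
from collections import deque

import numpy as np
from scipy import ndimage
from skimage.measure import label as _label

from .exceptions import DimensionError, PreconditionError

__all__ = [
    "make_marker",
    "grayscale_reconstruct_hybrid",
    "grayscale_reconstruct_iterative",
    "regional_maxima",
    "regional_maxima_oracle",
]


def make_marker(I: np.ndarray) -> np.ndarray:
    """Marker image J(p) = max(I(p) - 1, 0)."""
    I = np.asarray(I)
    return np.maximum(I.astype(np.int16) - 1, 0).astype(np.uint8)


def grayscale_reconstruct_hybrid(
    J: np.ndarray, I: np.ndarray, _pop: str = "fifo", _pop_seed: int | None = None
) -> np.ndarray:
    """Grayscale reconstruction (by dilation) of marker ``J`` under mask ``I``.

    Requires J <= I pointwise.  Returns J', the largest image <= I whose every
    connected ascent is seeded by J (8-connectivity).

    ``_pop`` selects the propagation queue discipline (``"fifo"`` or
    ``"random"`` with ``_pop_seed``); the result is pop-order independent and
    the option exists only so tests can assert that.
    """
    J = np.asarray(J)
    I = np.asarray(I)
    if J.shape != I.shape or J.ndim != 2:
        raise DimensionError(f"marker shape {J.shape} != mask shape {I.shape}")
    if (J.astype(np.int32) > I.astype(np.int32)).any():
        raise PreconditionError("marker exceeds mask: J(p) > I(p) somewhere")

    h, w = J.shape
    n = h * w
    j = J.astype(np.int32).ravel().tolist()
    m = I.astype(np.int32).ravel().tolist()

    # Raster scan: J(p) <- min(max({J(p)} U {J(q), q in N+(p)}), I(p)).
    # N+(p) = {up-left, up, up-right, left}.
    for p in range(n):
        r, c = divmod(p, w)
        s = j[p]
        if r > 0:
            q = p - w
            if c > 0 and j[q - 1] > s:
                s = j[q - 1]
            if j[q] > s:
                s = j[q]
            if c < w - 1 and j[q + 1] > s:
                s = j[q + 1]
        if c > 0 and j[p - 1] > s:
            s = j[p - 1]
        if s > m[p]:
            s = m[p]
        j[p] = s

    # Anti-raster scan with N-(p) = {right, down-left, down, down-right};
    # enqueue p if some q in N-(p) could still be raised by it.
    fifo: deque[int] = deque()
    for p in range(n - 1, -1, -1):
        r, c = divmod(p, w)
        neigh = []
        if c < w - 1:
            neigh.append(p + 1)
        if r < h - 1:
            q = p + w
            if c > 0:
                neigh.append(q - 1)
            neigh.append(q)
            if c < w - 1:
                neigh.append(q + 1)
        s = j[p]
        for q in neigh:
            if j[q] > s:
                s = j[q]
        if s > m[p]:
            s = m[p]
        j[p] = s
        jp = j[p]
        for q in neigh:
            if j[q] < jp and j[q] < m[q]:
                fifo.append(p)
                break

    # Propagation: pop p, raise any 8-neighbor q with J(q) < J(p), J(q) < I(q)
    # to min(J(p), I(q)) and enqueue it.
    rng = random.Random(_pop_seed) if _pop == "random" else None
    while fifo:
        if rng is None:
            p = fifo.popleft()
        else:
            k = rng.randrange(len(fifo))
            fifo.rotate(-k)
            p = fifo.popleft()
            fifo.rotate(k)
        r, c = divmod(p, w)
        jp = j[p]
        for dr in (-1, 0, 1):
            rr = r + dr
            if rr < 0 or rr >= h:
                continue
            base = rr * w
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                cc = c + dc
                if cc < 0 or cc >= w:
                    continue
                q = base + cc
                if j[q] < jp and j[q] < m[q]:
                    j[q] = jp if jp < m[q] else m[q]
                    fifo.append(q)

    return np.asarray(j, dtype=np.uint8).reshape(h, w)


def grayscale_reconstruct_iterative(J: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Naive reconstruction oracle: iterate min(dilate8(J), I) to a fixed point."""
    J = np.asarray(J).astype(np.int32)
    I = np.asarray(I).astype(np.int32)
    if (J > I).any():
        raise PreconditionError("marker exceeds mask")
    footprint = np.ones((3, 3), dtype=bool)
    while True:
        nxt = np.minimum(ndimage.grey_dilation(J, footprint=footprint), I)
        if np.array_equal(nxt, J):
            return J.astype(np.uint8)
        J = nxt


def regional_maxima(I: np.ndarray) -> np.ndarray:
    """Binary map R with R(p) = 1 iff I(p) - J'(p) = 1 (J' = reconstruction of I-1)."""
    I = np.asarray(I)
    Jp = grayscale_reconstruct_hybrid(make_marker(I), I)
    return (I.astype(np.int16) - Jp.astype(np.int16) == 1).astype(np.uint8)


def regional_maxima_oracle(I: np.ndarray) -> np.ndarray:
    """Definition-based oracle: label 8-connected constant plateaus and mark a
    plateau iff every pixel adjacent to it has a strictly lower value.

    Intended for small test images only.  Pixels with I = 0 are excluded to
    match the reconstruction route's "difference equals 1" rule.
    """
    I = np.asarray(I).astype(np.int32)
    labels = _label(I, background=-1, connectivity=2)
    out = np.zeros(I.shape, dtype=np.uint8)
    footprint = np.ones((3, 3), dtype=bool)
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        t = I[mask].flat[0]
        if t == 0:
            continue
        boundary = ndimage.binary_dilation(mask, structure=footprint) & ~mask
        if not boundary.any() or (I[boundary] < t).all():
            out[mask] = 1
    return out
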