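"""Raster image and coordinate-table I/O.

Images are plain numpy arrays: a grayscale image is a 2-D ``uint8`` array
(``GrayImage8``), an RGB image a 3-D ``uint8`` array with three channels
(``RGBImage8``).  Coordinates follow the array convention: 0-based
``(row, col)``, row-major.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import ImageFormatError

__all__ = [
    "read_image",
    "extract_input_channel",
    "write_gray_png",
    "write_nuclei_csv",
    "read_nuclei_csv",
    "write_kernel_txt",
]


def _to_uint8_depth(arr: np.ndarray) -> np.ndarray:
    """Normalize integer bit depth to 8 bits/channel (linear rescale)."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.rint(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scaled = (arr.astype(np.float64) - info.min) * (255.0 / (info.max - info.min))
        return np.rint(scaled).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        # float images are assumed to lie in [0, 1]
        return np.rint(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    raise ImageFormatError(f"unsupported pixel dtype {arr.dtype}")


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or TIFF image as ``uint8``, grayscale or RGB.

    16-bit inputs are linearly rescaled into [0, 255].  An alpha channel, if
    present, is dropped.

    Raises
    ------
    ImageFormatError
        If the file cannot be read as a raster image.
    """
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # backend plugins raise heterogeneous error types
        raise ImageFormatError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[-1] != 3):
        raise ImageFormatError(
            f"{path!r}: expected a grayscale or 3-channel image, got shape {arr.shape}"
        )
    return _to_uint8_depth(arr)


def extract_input_channel(img: np.ndarray, complement: bool = False) -> np.ndarray:
    """Extract the red channel of an RGB image as the pipeline's grayscale input.

    With ``complement=True`` every value v is replaced by 255 - v (hematoxylin
    renders nuclei dark in the red channel; the complement makes them bright).
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ImageFormatError(f"expected an RGB image, got shape {img.shape}")
    red = img[..., 0].astype(np.uint8)
    if complement:
        red = (255 - red.astype(np.int16)).astype(np.uint8)
    return red


def write_gray_png(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a ``uint8`` grayscale image (or 0/1 binary map, scaled to 0/255) as PNG."""
    img = np.asarray(img)
    if img.dtype == bool or (img.dtype != np.uint8 and img.max(initial=0) <= 1):
        img = (img.astype(np.uint8) * 255)
    iio.imwrite(os.fspath(path), img.astype(np.uint8))


def write_nuclei_csv(nuclei: np.ndarray, path: str | os.PathLike) -> None:
    """Write detected nuclei centers to CSV with header ``row,col``.

    Coordinates are real-valued, 0-based, row-major pixel units.
    """
    arr = np.asarray(nuclei, dtype=float).reshape(-1, 2)
    pd.DataFrame(arr, columns=["row", "col"]).to_csv(path, index=False)


def read_nuclei_csv(path: str | os.PathLike) -> np.ndarray:
    """Read a nuclei CSV written by :func:`write_nuclei_csv` back as an (n, 2) array."""
    df = pd.read_csv(path)
    return df[["row", "col"]].to_numpy(dtype=float)


def write_kernel_txt(weights: np.ndarray, path: str | os.PathLike) -> None:
    """Export a filter as a plain-text matrix (one row per line, space-separated)."""
    np.savetxt(path, np.asarray(weights, dtype=float), fmt="%.12g")
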