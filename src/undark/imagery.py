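"""Image containers, intensity conventions and file I/O.

Images are plain :class:`numpy.ndarray` objects:

* RGB rasters are ``(H, W, 3)`` float64 arrays with intensities in ``[0, 1]``
  and channels ordered R, G, B;
* grayscale images are ``(H, W)`` float64 arrays in ``[0, 1]``.

Files are exchanged as 8-bit unsigned PNG/JPEG/TIFF; intensities are divided
by 255 on load and rescaled (with rounding) on save.  The 255-based inversion
used throughout low-light dehazing, ``x̄ = 255 − x``, therefore becomes
``x̄ = 1 − x`` on the internal scale.
"""

from __future__ import annotations

import logging
import os
from typing import Union

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GRAY_WEIGHTS",
    "ImageFormatError",
    "as_raster",
    "invert",
    "to_grayscale",
    "read_image",
    "write_image",
]

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights for R, G, B.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

PathLike = Union[str, "os.PathLike[str]"]


class ImageFormatError(ValueError):
    """Raised for undecodable files or unsupported layouts/bit depths."""


def as_raster(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce *arr* into the internal RGB raster convention.

    Accepts any array of shape ``(H, W, 3)``; returns a float64 copy clipped
    to ``[0, 1]``.  Integer arrays are assumed to be 8-bit and divided by 255.
    """
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64, copy=True)
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    return np.clip(arr, 0.0, 1.0)


def invert(img: np.ndarray) -> np.ndarray:
    """Photometric inversion ``v ↦ 1 − v`` (the 255−x rule on [0, 1]).

    Works on RGB rasters and grayscale maps alike; an involution.
    """
    return 1.0 - np.asarray(img, dtype=np.float64)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Weighted luminance (BT.601: 0.299 R + 0.587 G + 0.114 B)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {img.shape}")
    return img @ GRAY_WEIGHTS


def read_image(path: PathLike) -> np.ndarray:
    """Read an 8-bit PNG/JPEG/TIFF as an ``(H, W, 3)`` float raster.

    Single-channel files are promoted to three identical channels; alpha
    channels are dropped with a logged warning.  Missing files raise the
    usual ``OSError``; undecodable or non-8-bit files raise
    :class:`ImageFormatError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failures vary by backend
        raise ImageFormatError(f"cannot decode image file {path}: {exc}") from exc
    if arr.dtype == np.bool_:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise ImageFormatError(
            f"unsupported bit depth {arr.dtype} in {path}; only 8-bit images are supported"
        )
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] in (2, 4):
        logger.warning("dropping alpha channel while reading %s", path)
        if arr.shape[2] == 2:  # luminance + alpha
            arr = np.repeat(arr[:, :, :1], 3, axis=2)
        else:
            arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"unsupported image layout {arr.shape} in {path}")
    return arr.astype(np.float64) / 255.0


def write_image(img: np.ndarray, path: PathLike) -> None:
    """Write a raster or grayscale map as an 8-bit image file."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D array, got shape {img.shape}")
    data = np.rint(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, data)
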