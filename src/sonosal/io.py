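"""Image I/O and the shared array conventions used across the package.

All modules operate on float64 arrays indexed ``(row, col)`` with 0-based,
row-major indexing; row 0 is the top of the image.  Gray values live in
``[0, 255]`` as reals — quantization back to 8-bit integers happens only
when a file is written.  B-mode frames exported by scanners are commonly
stored as 3-channel bitmaps with (nearly) equal channels, so readers return
the three channel planes explicitly.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Tuple

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk as _disk_coords

if TYPE_CHECKING:  # pragma: no cover
    from .localization import LocalizationResult

__all__ = [
    "MIN_SIZE",
    "ValidationError",
    "validate_gray",
    "read_image",
    "write_gray",
    "write_overlay",
]

#: Minimum accepted image side.  A 9-level half-resolution pyramid of anything
#: smaller degenerates immediately, so smaller inputs are rejected outright.
MIN_SIZE = 32


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def validate_gray(pixels: np.ndarray, *, min_size: int = MIN_SIZE) -> np.ndarray:
    """Validate and coerce a 2-D gray image to float64 in [0, 255].

    Raises
    ------
    ValidationError
        If the array is not 2-D, too small, non-finite, or out of range.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D gray image, got ndim={arr.ndim}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValidationError(
            f"image {arr.shape} smaller than minimum {min_size}x{min_size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("gray values must lie in [0, 255]")
    return arr


def read_image(path: str | os.PathLike) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a BMP/PNG/TIFF image and return its (r, g, b) channel planes.

    Single-channel files are broadcast so that r = g = b.  An alpha channel,
    if present, is dropped.  Planes are float64 in [0, 255].
    """
    try:
        raw = iio.imread(os.fspath(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"could not read image file {path!r}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValidationError(f"image file {path!r} decodes to a zero-sized array")
    if raw.dtype == np.uint16:
        raw = raw.astype(np.float64) / 257.0  # 16-bit TIFFs down to 8-bit scale
    raw = raw.astype(np.float64)
    if raw.ndim == 2:
        r = g = b = raw
    elif raw.ndim == 3 and raw.shape[2] in (3, 4):
        r, g, b = raw[:, :, 0], raw[:, :, 1], raw[:, :, 2]
    elif raw.ndim == 3 and raw.shape[2] == 1:
        r = g = b = raw[:, :, 0]
    else:
        raise ValidationError(f"unsupported image layout {raw.shape} in {path!r}")
    validate_gray(r)
    return r.copy(), g.copy(), b.copy()


def write_gray(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D array as an 8-bit grayscale image (values clipped to [0,255])."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0, 255)
    out = np.rint(arr).astype(np.uint8)
    try:
        iio.imwrite(os.fspath(path), out)
    except Exception as exc:
        raise IOError(f"could not write image file {path!r}: {exc}") from exc


def _draw_circle(rgb: np.ndarray, center: Tuple[int, int], radius: float,
                 color: Tuple[int, int, int], thickness: int = 2) -> None:
    h, w = rgb.shape[:2]
    rr_all, cc_all = _disk_coords(center, radius + thickness, shape=(h, w))
    inner = set(zip(*_disk_coords(center, max(radius - thickness, 0), shape=(h, w))))
    for r, c in zip(rr_all, cc_all):
        if (r, c) not in inner:
            rgb[r, c] = color


def write_overlay(image: np.ndarray, result: "LocalizationResult",
                  path: str | os.PathLike) -> None:
    """Render the attention sequence on top of the image and write a PNG.

    The accepted focus-of-attention circle is drawn in green; rejected
    candidates in red.  The result must contain at least one fixation.
    """
    gray = validate_gray(image)
    if not result.fixations:
        raise ValidationError("localization result contains no fixations to draw")
    rgb = np.stack([np.rint(gray).astype(np.uint8)] * 3, axis=-1)
    for foa in result.fixations:
        color = (0, 220, 0) if foa.accepted else (230, 40, 40)
        _draw_circle(rgb, (foa.row, foa.col), foa.radius, color)
    try:
        iio.imwrite(os.fspath(path), rgb)
    except Exception as exc:
        raise IOError(f"could not write overlay {path!r}: {exc}") from exc
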