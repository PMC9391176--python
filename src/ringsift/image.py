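"""Image loading and preprocessing: graying and median filtering.

All downstream stages consume :class:`GrayImage` — a float64 intensity grid
on the 0–255 scale. Coordinate convention throughout the package: 0-based,
``x`` = column rightward, ``y`` = row downward, pixel centers at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from PIL import Image, UnidentifiedImageError

from .errors import InputError, ParameterError

# ITU-R BT.601 luminance weights for RGB -> gray collapse.
_BT601 = np.array([0.299, 0.587, 0.114])

MIN_SIZE = 3  # Sobel needs a full 3x3 window


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale intensity grid (float64, 0–255 scale)."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InputError(f"GrayImage needs a 2-D grid, got shape {px.shape}")
        if px.shape[0] < MIN_SIZE or px.shape[1] < MIN_SIZE:
            raise InputError(
                f"image too small: {px.shape[1]}x{px.shape[0]} "
                f"(minimum {MIN_SIZE}x{MIN_SIZE})"
            )
        if not np.all(np.isfinite(px)):
            raise InputError("image contains non-finite intensities")
        if px.min() < 0 or px.max() > 255:
            raise InputError(
                f"intensities outside [0, 255]: min {px.min():g}, max {px.max():g}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_gray(path) -> GrayImage:
    """Read a PNG/TIFF/JPEG file and collapse to BT.601 luminance.

    8-bit grayscale values are preserved exactly; RGB pixels map to
    ``0.299 R + 0.587 G + 0.114 B``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file does not exist: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"zero-sized image: {path}")
    return from_array(arr)


def from_array(arr: np.ndarray) -> GrayImage:
    """Build a GrayImage from an 8-bit (or float 0–255) gray/RGB/RGBA array."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise InputError(f"unsupported channel count: {arr.shape[2]}")
        arr = arr @ _BT601
    elif arr.ndim != 2:
        raise InputError(f"unsupported image dimensionality: {arr.ndim}")
    return GrayImage(arr)


def median_filter(img: GrayImage, window: int = 3) -> GrayImage:
    """Replace each pixel by the median of its ``window``×``window`` neighborhood.

    Borders use edge replication; output dimensions are unchanged. The window
    must be odd so that the neighborhood has a well-defined center.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"median window must be odd and >= 3, got {window}")
    out = ndi.median_filter(img.pixels, size=window, mode="nearest")
    return GrayImage(out)
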