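"""Sobel-based first- and second-order gradient fields.

Instead of the pixel-difference gradients of classical SIFT, every scale-space
layer gets a Sobel gradient: the 3x3 Sobel templates combine Gaussian
smoothing with differentiation, which suppresses noise and weakens unstable
edge responses. A *second-order* field — the Sobel gradient of the
first-order gradient-magnitude raster — is what the orientation and
descriptor stages consume by default (configurable).

Orientation convention: quadrant-aware ``atan2(Gy, Gx)``, radians in
(−π, π], 0 pointing along +x (column direction), positive toward +y
(row direction). At zero magnitude the orientation is defined as 0; such
pixels carry zero weight in every histogram, so the convention is
unobservable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .errors import ParameterError
from .image import GrayImage

# Horizontal (x) and vertical (y) Sobel templates, applied as correlation
# filters (a ramp I(x,y)=x gives interior response +8 on the x template).
SOBEL_BX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_BY = np.array([[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]])


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient magnitude and orientation at one scale layer."""

    magnitude: np.ndarray  # >= 0, same shape as source
    orientation: np.ndarray  # radians in (-pi, pi]; 0 where magnitude is 0
    scale_sigma: float  # Gaussian scale of the layer this was computed on

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def sobel_convolve(pixels, axis: str) -> np.ndarray:
    """Apply the 3x3 Sobel template along ``axis`` ('horizontal' or 'vertical').

    Accepts a GrayImage or a bare 2-D array; borders are edge-replicated and
    the output keeps the input shape. Returns a signed float grid.
    """
    if isinstance(pixels, GrayImage):
        pixels = pixels.pixels
    arr = np.asarray(pixels, dtype=np.float64)
    if axis == "horizontal":
        kernel = SOBEL_BX
    elif axis == "vertical":
        kernel = SOBEL_BY
    else:
        raise ParameterError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return ndi.correlate(arr, kernel, mode="nearest")


def _field_from_responses(gx: np.ndarray, gy: np.ndarray, sigma: float) -> GradientField:
    mag = np.hypot(gx, gy)
    ori = np.arctan2(gy, gx)
    ori[mag == 0] = 0.0
    # atan2 returns [-pi, pi]; fold -pi onto +pi so the range is (-pi, pi]
    ori[ori == -np.pi] = np.pi
    return GradientField(magnitude=mag, orientation=ori, scale_sigma=float(sigma))


def first_order_field(img, sigma: float) -> GradientField:
    """First-order Sobel gradient field of a Gaussian scale-space layer.

    ``img`` is expected to already be the blurred layer at scale ``sigma``
    (the scale-space builder applies the Gaussian upstream).
    """
    gx = sobel_convolve(img, "horizontal")
    gy = sobel_convolve(img, "vertical")
    return _field_from_responses(gx, gy, sigma)


def second_order_field(first: GradientField) -> GradientField:
    """Sobel gradient of the first-order magnitude raster.

    This re-differentiated field gives each pixel the "new" gradient size and
    direction used by orientation assignment and descriptor accumulation.
    """
    gx2 = sobel_convolve(first.magnitude, "horizontal")
    gy2 = sobel_convolve(first.magnitude, "vertical")
    return _field_from_responses(gx2, gy2, first.scale_sigma)
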