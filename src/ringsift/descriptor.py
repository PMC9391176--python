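"""The 64-dimension concentric-ring descriptor.

The classical SIFT 16x16 square grid (4x4 cells x 8 orientations = 128
dimensions) is replaced by 8 concentric rings around the keypoint, each
accumulating an 8-bin orientation histogram: 8 rings x 8 bins = 64
dimensions, half the size. Pixels closer to the keypoint get larger
weights (a Gaussian falloff over the ring index), gradient orientations are
measured relative to the keypoint's main direction (rotation invariance),
and the finished vector is unit-normalized (illumination invariance).

Layout: ring-major — components [8*r : 8*r+8] belong to ring ``r`` (ring 0
innermost), bin 0 centered on the main direction, 45 degrees per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .gradients import GradientField
from .keypoints import Keypoint

N_RINGS = 8
N_BINS = 8
DESCRIPTOR_SIZE = N_RINGS * N_BINS  # 64
_RING_SIGMA = 4.0  # Gaussian falloff scale of the ring weights (in rings)


@dataclass(frozen=True)
class Descriptor:
    """A unit-normalized 64-component concentric-ring feature vector."""

    values: np.ndarray  # (64,), non-negative, unit L2 norm
    keypoint: Keypoint

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (DESCRIPTOR_SIZE,):
            raise ParameterError(f"descriptor must have {DESCRIPTOR_SIZE} components")
        object.__setattr__(self, "values", v)


def ring_weight(ring_index: int) -> float:
    """Weight of a ring: Gaussian falloff in the ring index, ring 0 -> 1.0.

    Closer pixels influence the descriptor more; the falloff
    ``exp(-r^2 / (2 * 4^2))`` keeps the outermost ring at ~22% of the
    innermost while every ring stays strictly positive.
    """
    if not 0 <= ring_index < N_RINGS:
        raise ParameterError(f"ring_index must be in 0..{N_RINGS - 1}, got {ring_index}")
    return float(np.exp(-(ring_index**2) / (2.0 * _RING_SIGMA**2)))


_RING_WEIGHTS = np.array([np.exp(-(r**2) / (2.0 * _RING_SIGMA**2)) for r in range(N_RINGS)])


def build_descriptor(
    kp: Keypoint,
    field: GradientField,
    radius_per_ring: float = 1.0,
    scale_with_sigma: bool = True,
) -> Descriptor | None:
    """Accumulate the 64-dim concentric-ring descriptor for one keypoint.

    Every pixel of the disc of radius ``8 * ring_width`` around the keypoint
    (on its octave grid) contributes its gradient magnitude, scaled by the
    ring weight, to the orientation bin of its gradient direction rotated by
    ``-main_theta``, with linear interpolation between the two adjacent bins.
    ``ring_width = radius_per_ring * sigma_oct / base_sigma`` when
    ``scale_with_sigma`` (making the support scale-covariant), else a fixed
    ``radius_per_ring`` pixels. Pixels exactly on a ring boundary fall to
    the inner ring (floor rule). Returns None when nothing accumulates
    (featureless or fully off-image neighborhood).
    """
    if kp.main_theta is None:
        raise ParameterError("keypoint has no main orientation; run assign_orientations first")
    H, W = field.shape
    if scale_with_sigma:
        # sigma_oct / 1.6 == k^layer: ring width grows with the layer scale
        ring_width = radius_per_ring * kp.sigma_oct / 1.6
    else:
        ring_width = radius_per_ring
    outer = N_RINGS * ring_width

    cx, cy = kp.x_oct, kp.y_oct
    x0 = max(int(np.floor(cx - outer)), 0)
    x1 = min(int(np.ceil(cx + outer)), W - 1)
    y0 = max(int(np.floor(cy - outer)), 0)
    y1 = min(int(np.ceil(cy + outer)), H - 1)
    if x1 < x0 or y1 < y0:
        return None

    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dist = np.hypot(xs - cx, ys - cy)
    inside = dist < outer
    if not np.any(inside):
        return None

    ring = np.minimum((dist[inside] / ring_width).astype(int), N_RINGS - 1)
    mag = field.magnitude[y0 : y1 + 1, x0 : x1 + 1][inside]
    ori = field.orientation[y0 : y1 + 1, x0 : x1 + 1][inside]

    # orientation relative to the main direction, in bin units
    rel = np.mod(ori - kp.main_theta, 2.0 * np.pi)
    pos = rel / (2.0 * np.pi / N_BINS)  # in [0, 8)
    b0 = np.floor(pos).astype(int) % N_BINS
    frac = pos - np.floor(pos)
    b1 = (b0 + 1) % N_BINS

    w = mag * _RING_WEIGHTS[ring]
    hist = np.zeros((N_RINGS, N_BINS))
    np.add.at(hist, (ring, b0), w * (1.0 - frac))
    np.add.at(hist, (ring, b1), w * frac)

    flat = hist.ravel()
    norm = np.linalg.norm(flat)
    if norm == 0:
        return None
    return Descriptor(values=flat / norm, keypoint=kp)


def descriptors_to_table(descs: list[Descriptor]) -> np.ndarray:
    """Plain-text-friendly table: x, y, sigma, theta, then the 64 values."""
    rows = [
        np.concatenate([[d.keypoint.x, d.keypoint.y, d.keypoint.sigma,
                         d.keypoint.main_theta], d.values])
        for d in descs
    ]
    return np.array(rows) if rows else np.empty((0, 4 + DESCRIPTOR_SIZE))
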