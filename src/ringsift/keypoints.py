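"""Scale-space keypoint detection and orientation assignment.

Detection is classical SIFT: a Gaussian pyramid, difference-of-Gaussian
(DoG) layers, 26-neighbor extrema, quadratic sub-pixel refinement,
low-contrast and edge-ratio rejection (Lowe's defaults). What differs from
classical SIFT is the gradient used afterwards: orientations come from the
Sobel gradient fields of :mod:`ringsift.gradients`, not pixel differences.

The pyramid starts at the input resolution (no initial 2x upsampling), so a
``min(width, height)`` of at least 16 per octave gives
``floor(log2(min_dim / 16)) + 1`` octaves by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.ndimage as ndi

from .errors import ParameterError
from .gradients import GradientField
from .image import GrayImage

OCTAVE_FLOOR = 16  # smallest octave base dimension allowed by default
_ASSUMED_INPUT_BLUR = 0.5  # camera/antialias blur assumed on the raw image


@dataclass
class Keypoint:
    """A located scale-space extremum.

    ``x``/``y`` are sub-pixel coordinates in the *original* image;
    ``x_oct``/``y_oct`` the same position on the keypoint's octave grid,
    where orientation and descriptor accumulation happen. ``sigma`` is the
    absolute detection scale, ``sigma_oct`` the octave-relative scale.
    """

    x: float
    y: float
    sigma: float
    octave: int
    layer: int
    x_oct: float
    y_oct: float
    sigma_oct: float
    response: float = 0.0
    main_theta: float | None = None
    aux_thetas: list[float] = dc_field(default_factory=list)


@dataclass(frozen=True)
class ScaleSpace:
    """Gaussian pyramid plus DoG layers for one image."""

    gaussians: list[list[np.ndarray]]  # [octave][layer], intensities in [0,1]
    dogs: list[np.ndarray]  # [octave] -> (layers+2, H, W) stack
    base_sigma: float
    layers_per_octave: int

    @property
    def n_octaves(self) -> int:
        return len(self.gaussians)

    @property
    def k(self) -> float:
        return 2.0 ** (1.0 / self.layers_per_octave)

    def layer_sigma(self, layer: int) -> float:
        """Octave-relative Gaussian scale of a pyramid layer."""
        return self.base_sigma * self.k**layer


def default_octaves(width: int, height: int, floor: int = OCTAVE_FLOOR) -> int:
    """Number of octaves keeping every octave at least ``floor`` pixels wide."""
    m = min(width, height)
    if m < floor:
        return 1
    return int(math.floor(math.log2(m / floor))) + 1


def build_scale_space(
    img: GrayImage,
    octaves: int | None = None,
    layers_per_octave: int = 3,
    base_sigma: float = 1.6,
) -> ScaleSpace:
    """Build the Gaussian pyramid and its DoG stacks.

    ``layers_per_octave`` is the number of DoG layers searched per octave
    (Lowe's s); each octave holds ``s + 3`` Gaussian images with scale step
    ``k = 2^(1/s)`` and is downsampled by 2 to seed the next.
    """
    if layers_per_octave < 3:
        raise ParameterError(f"layers_per_octave must be >= 3, got {layers_per_octave}")
    if octaves is None:
        octaves = default_octaves(img.width, img.height)
    if octaves < 1:
        raise ParameterError(f"octaves must be >= 1, got {octaves}")
    min_dim = min(img.width, img.height)
    if min_dim // 2 ** (octaves - 1) < 8:
        raise ParameterError(
            f"image {img.width}x{img.height} too small for {octaves} octaves"
        )

    s = layers_per_octave
    k = 2.0 ** (1.0 / s)
    base = img.pixels / 255.0
    # bring the raw image (assumed blur 0.5) up to base_sigma
    delta = math.sqrt(max(base_sigma**2 - _ASSUMED_INPUT_BLUR**2, 0.01))
    current = ndi.gaussian_filter(base, delta, mode="nearest")

    # incremental blurs within an octave: sigma_l = base_sigma * k^l
    increments = [
        base_sigma * k**l * math.sqrt(k**2 - 1.0) for l in range(s + 2)
    ]

    gaussians: list[list[np.ndarray]] = []
    dogs: list[np.ndarray] = []
    for _o in range(octaves):
        layers = [current]
        for inc in increments:
            layers.append(ndi.gaussian_filter(layers[-1], inc, mode="nearest"))
        gaussians.append(layers)
        dogs.append(np.stack([layers[i + 1] - layers[i] for i in range(s + 2)]))
        # layer s has scale 2*base_sigma: decimate it to seed the next octave
        current = layers[s][::2, ::2]
    return ScaleSpace(gaussians=gaussians, dogs=dogs,
                      base_sigma=base_sigma, layers_per_octave=s)


def _candidate_extrema(dog: np.ndarray, prethreshold: float) -> np.ndarray:
    """26-neighbor extrema candidates in a (L, H, W) DoG stack.

    Returns an (n, 3) int array of (layer, row, col) for interior layers.
    """
    L, H, W = dog.shape
    if L < 3 or H < 3 or W < 3:
        return np.empty((0, 3), dtype=int)
    core = dog[1:-1, 1:-1, 1:-1]
    is_max = np.ones(core.shape, dtype=bool)
    is_min = np.ones(core.shape, dtype=bool)
    for dl in (-1, 0, 1):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dl == 0 and dr == 0 and dc == 0:
                    continue
                nb = dog[1 + dl : L - 1 + dl, 1 + dr : H - 1 + dr, 1 + dc : W - 1 + dc]
                is_max &= core > nb
                is_min &= core < nb
    mask = (is_max | is_min) & (np.abs(core) > prethreshold)
    l, r, c = np.nonzero(mask)
    return np.stack([l + 1, r + 1, c + 1], axis=1)


def _refine(dog: np.ndarray, l: int, r: int, c: int,
            contrast_threshold: float, edge_ratio: float):
    """Quadratic sub-pixel refinement with contrast and edge-ratio tests.

    Returns (layer, row, col, d_layer, d_row, d_col, value) or None.
    """
    L, H, W = dog.shape
    for _ in range(5):
        d = dog
        g = np.array([
            (d[l + 1, r, c] - d[l - 1, r, c]) / 2.0,
            (d[l, r + 1, c] - d[l, r - 1, c]) / 2.0,
            (d[l, r, c + 1] - d[l, r, c - 1]) / 2.0,
        ])
        dll = d[l + 1, r, c] + d[l - 1, r, c] - 2 * d[l, r, c]
        drr = d[l, r + 1, c] + d[l, r - 1, c] - 2 * d[l, r, c]
        dcc = d[l, r, c + 1] + d[l, r, c - 1] - 2 * d[l, r, c]
        dlr = (d[l + 1, r + 1, c] - d[l + 1, r - 1, c]
               - d[l - 1, r + 1, c] + d[l - 1, r - 1, c]) / 4.0
        dlc = (d[l + 1, r, c + 1] - d[l + 1, r, c - 1]
               - d[l - 1, r, c + 1] + d[l - 1, r, c - 1]) / 4.0
        drc = (d[l, r + 1, c + 1] - d[l, r + 1, c - 1]
               - d[l, r - 1, c + 1] + d[l, r - 1, c - 1]) / 4.0
        hess = np.array([[dll, dlr, dlc], [dlr, drr, drc], [dlc, drc, dcc]])
        try:
            offset = -np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(offset) < 0.5):
            break
        l += int(round(offset[0]))
        r += int(round(offset[1]))
        c += int(round(offset[2]))
        if not (1 <= l < L - 1 and 1 <= r < H - 1 and 1 <= c < W - 1):
            return None
    else:
        return None

    value = d[l, r, c] + 0.5 * float(g @ offset)
    if abs(value) < contrast_threshold:
        return None
    # edge rejection on the 2x2 spatial Hessian
    tr = drr + dcc
    det = drr * dcc - drc * drc
    if det <= 0 or tr * tr * edge_ratio >= (edge_ratio + 1) ** 2 * det:
        return None
    return l, r, c, offset[0], offset[1], offset[2], value


def detect_extrema(
    ss: ScaleSpace,
    contrast_threshold: float = 0.03,
    edge_ratio: float = 10.0,
) -> list[Keypoint]:
    """Locate refined DoG extrema across all octaves (orientations unset)."""
    s = ss.layers_per_octave
    k = ss.k
    kps: list[Keypoint] = []
    for o, dog in enumerate(ss.dogs):
        scale = 2.0**o
        for l0, r0, c0 in _candidate_extrema(dog, 0.5 * contrast_threshold):
            res = _refine(dog, int(l0), int(r0), int(c0),
                          contrast_threshold, edge_ratio)
            if res is None:
                continue
            l, r, c, dl, dr, dc, value = res
            x_oct = c + dc
            y_oct = r + dr
            sigma_oct = ss.base_sigma * k ** (l + dl)
            kps.append(Keypoint(
                x=x_oct * scale,
                y=y_oct * scale,
                sigma=sigma_oct * scale,
                octave=o,
                layer=int(l),
                x_oct=float(x_oct),
                y_oct=float(y_oct),
                sigma_oct=float(sigma_oct),
                response=float(abs(value)),
            ))
    return kps


N_ORI_BINS = 36
AUX_PEAK_RATIO = 0.8


def assign_orientations(kp: Keypoint, field: GradientField) -> Keypoint | None:
    """Assign a main (and possibly auxiliary) orientation from a gradient field.

    A 36-bin histogram of gradient orientations over a Gaussian-weighted
    circular neighborhood of radius 3·(1.5·sigma), magnitude-weighted; the
    interpolated peak gives ``main_theta``, every other local peak reaching
    80% of the maximum an auxiliary orientation. Returns None when the
    keypoint has no usable neighborhood (off-image or zero gradient).
    """
    H, W = field.shape
    sigma_w = 1.5 * kp.sigma_oct
    radius = max(int(round(3.0 * sigma_w)), 1)
    cx, cy = kp.x_oct, kp.y_oct
    x0, x1 = int(math.floor(cx - radius)), int(math.ceil(cx + radius))
    y0, y1 = int(math.floor(cy - radius)), int(math.ceil(cy + radius))
    if x1 < 0 or y1 < 0 or x0 >= W or y0 >= H:
        return None
    x0c, x1c = max(x0, 0), min(x1, W - 1)
    y0c, y1c = max(y0, 0), min(y1, H - 1)
    ys, xs = np.mgrid[y0c : y1c + 1, x0c : x1c + 1]
    dx = xs - cx
    dy = ys - cy
    r2 = dx * dx + dy * dy
    mask = r2 <= radius * radius
    if not np.any(mask):
        return None
    mag = field.magnitude[y0c : y1c + 1, x0c : x1c + 1][mask]
    ori = field.orientation[y0c : y1c + 1, x0c : x1c + 1][mask]
    weights = mag * np.exp(-r2[mask] / (2.0 * sigma_w**2))
    if not np.any(weights > 0):
        return None

    bin_width = 2.0 * np.pi / N_ORI_BINS
    bins = np.round(ori / bin_width).astype(int) % N_ORI_BINS
    hist = np.bincount(bins, weights=weights, minlength=N_ORI_BINS)
    # two circular [1,2,1]/4 smoothing passes stabilize the peak
    for _ in range(2):
        hist = (np.roll(hist, 1) + 2.0 * hist + np.roll(hist, -1)) / 4.0
    peak = hist.max()
    if peak <= 0:
        return None

    thetas: list[float] = []
    for b in range(N_ORI_BINS):
        left = hist[(b - 1) % N_ORI_BINS]
        right = hist[(b + 1) % N_ORI_BINS]
        if hist[b] >= AUX_PEAK_RATIO * peak and hist[b] > left and hist[b] > right:
            denom = left - 2.0 * hist[b] + right
            delta = 0.0 if denom == 0 else 0.5 * (left - right) / denom
            theta = (b + delta) * bin_width
            theta = math.remainder(theta, 2.0 * np.pi)  # -> (-pi, pi]
            if theta <= -np.pi:
                theta += 2.0 * np.pi
            thetas.append((float(hist[b]), float(theta)))
    if not thetas:
        # flat histogram (e.g. perfectly uniform orientations): no evidence
        return None
    thetas.sort(key=lambda t: -t[0])
    kp.main_theta = thetas[0][1]
    kp.aux_thetas = [t for _, t in thetas[1:]]
    return kp


def expand_orientations(kps: list[Keypoint]) -> list[Keypoint]:
    """Duplicate keypoints so each carries exactly one reference direction."""
    out: list[Keypoint] = []
    for kp in kps:
        if kp.main_theta is None:
            continue
        out.append(kp)
        for theta in kp.aux_thetas:
            dup = Keypoint(
                x=kp.x, y=kp.y, sigma=kp.sigma, octave=kp.octave, layer=kp.layer,
                x_oct=kp.x_oct, y_oct=kp.y_oct, sigma_oct=kp.sigma_oct,
                response=kp.response, main_theta=theta, aux_thetas=[],
            )
            out.append(dup)
    return out
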