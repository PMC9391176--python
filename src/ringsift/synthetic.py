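"""Synthetic fixtures with exact ground truth.

Everything the test suite and the acceptance checks consume is generated
here: textured images, warped image pairs with a known homography, planted
correspondence sets with controlled outlier fractions, multi-camera rigs
with planted 3-D points, and a renderable two-plane scene for image-level
reconstruction. All generators are pure functions of their arguments
(including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import ProjectiveTransform, warp

from .errors import InputError, ParameterError
from .image import GrayImage
from .robust import Homography
from .sfm import CameraIntrinsics, projection_matrix, reproject


# ---------------------------------------------------------------- textures

def make_texture(width: int = 256, height: int = 256, seed: int = 0,
                 style: str = "filtered-noise", n_blobs: int = 40) -> GrayImage:
    """A deterministic textured image rich enough for keypoint detection.

    Styles: ``filtered-noise`` (band-limited white noise, the default
    workhorse — maximal fine detail), ``multiband-noise`` (noise mixed over
    four spatial scales, for renderings that minify the texture),
    ``blobs`` (Gaussian bumps of both signs on mid-gray), ``checker-noise``
    (a checkerboard with noise).
    """
    if width < 64 or height < 64:
        raise ParameterError("texture dimensions must be >= 64")
    rng = np.random.default_rng(seed)
    if style == "filtered-noise":
        img = ndi.gaussian_filter(rng.standard_normal((height, width)), 1.8)
    elif style == "multiband-noise":
        img = np.zeros((height, width))
        for s, a in ((1.8, 1.0), (3.6, 0.5), (7.2, 0.3), (14.0, 0.2)):
            img += a * ndi.gaussian_filter(rng.standard_normal((height, width)), s) * s
    elif style == "blobs":
        img = np.zeros((height, width))
        ys, xs = np.mgrid[0:height, 0:width]
        centers: list[tuple[float, float]] = []
        attempts = 0
        while len(centers) < n_blobs and attempts < 100 * n_blobs:
            attempts += 1
            cx = rng.uniform(16, width - 16)
            cy = rng.uniform(16, height - 16)
            # keep blobs separated so each yields its own scale-space extremum
            if any(np.hypot(cx - px, cy - py) < 40 for px, py in centers):
                continue
            centers.append((cx, cy))
            s = rng.uniform(2.5, 3.8)
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.9, 1.0)
            img += amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * s * s))
    elif style == "checker-noise":
        ys, xs = np.mgrid[0:height, 0:width]
        img = (((xs // 16) + (ys // 16)) % 2).astype(float) - 0.5
        img += 0.35 * ndi.gaussian_filter(rng.standard_normal((height, width)), 1.5)
    else:
        raise ParameterError(f"unknown texture style: {style!r}")
    if style in ("filtered-noise", "multiband-noise"):
        # percentile stretch with clipping, like a photographic histogram:
        # a global min/max stretch lets a single extreme pixel crush the
        # contrast of everything else
        lo, hi = np.percentile(img, [2.0, 98.0])
    else:
        lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return GrayImage(np.full((height, width), 128.0))
    return GrayImage(np.clip((img - lo) / (hi - lo), 0.0, 1.0) * 255.0)


def make_blob_image(width: int, height: int, centers: np.ndarray,
                    sigma: float = 4.0, amplitude: float = 200.0) -> GrayImage:
    """Isolated bright Gaussian blobs at given (x, y) centers on black."""
    ys, xs = np.mgrid[0:height, 0:width]
    img = np.zeros((height, width))
    for cx, cy in np.atleast_2d(centers):
        img += amplitude * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    return GrayImage(np.clip(img, 0, 255))


# ------------------------------------------------------------- warp pairs

@dataclass
class WarpFixture:
    image_a: GrayImage
    image_b: GrayImage
    H_true: Homography
    valid_region: np.ndarray  # bool mask on image_a: warp lands inside image_b


def rotation_homography(theta_rad: float, center: tuple[float, float]) -> np.ndarray:
    """Rotation about an image point, as a 3x3 homography (x right, y down)."""
    cx, cy = center
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    T1 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    T2 = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    return T2 @ R @ T1


def similarity_homography(theta_rad: float, scale: float,
                          center: tuple[float, float]) -> np.ndarray:
    cx, cy = center
    c, s = scale * np.cos(theta_rad), scale * np.sin(theta_rad)
    T1 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    S = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    T2 = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    return T2 @ S @ T1


def make_warp_pair(
    base: GrayImage,
    seed: int = 0,
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    H: np.ndarray | None = None,
    blur_sigma: float = 0.0,
    gamma: float = 1.0,
    min_coverage: float = 0.25,
) -> WarpFixture:
    """Warp/degrade a base image with exact ground truth.

    ``image_b`` is the bilinear warp of ``image_a`` under ``H_true`` (a
    similarity about the image center unless an explicit projective ``H`` is
    given), optionally blurred and gamma-mapped afterwards. A matched
    keypoint pair (a, b) is *correct* iff ``||H_true·a - b|| <= 2 px``.
    """
    if H is not None:
        H_true = np.asarray(H, dtype=float)
    else:
        center = ((base.width - 1) / 2.0, (base.height - 1) / 2.0)
        H_true = similarity_homography(np.deg2rad(rotation_deg), scale, center)

    tform = ProjectiveTransform(matrix=np.linalg.inv(H_true))
    warped = warp(base.pixels / 255.0, tform, order=1, cval=0.0,
                  preserve_range=True)
    coverage_mask = warp(np.ones_like(base.pixels), tform, order=0, cval=0.0) > 0.5
    coverage = coverage_mask.mean()
    if coverage < min_coverage:
        raise InputError(f"warp maps only {coverage:.0%} of pixels into frame "
                         f"(minimum {min_coverage:.0%})")

    if blur_sigma > 0:
        warped = ndi.gaussian_filter(warped, blur_sigma, mode="nearest")
    if gamma != 1.0:
        warped = np.clip(warped, 0.0, 1.0) ** gamma
    image_b = GrayImage(np.clip(warped * 255.0, 0, 255))

    # valid region on image_a: pixels whose image under H_true is in frame
    ys, xs = np.mgrid[0 : base.height, 0 : base.width]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    Hm = Homography(H_true)
    mapped = Hm.apply(pts)
    inside = ((mapped[:, 0] >= 0) & (mapped[:, 0] <= base.width - 1)
              & (mapped[:, 1] >= 0) & (mapped[:, 1] <= base.height - 1))
    valid = inside.reshape(base.height, base.width)
    return WarpFixture(image_a=base, image_b=image_b, H_true=Hm, valid_region=valid)


# ---------------------------------------------------- planted match sets

def make_planted_matches(
    n_inliers: int = 24,
    n_outliers: int = 6,
    seed: int = 0,
    extent: float = 256.0,
    H: np.ndarray | None = None,
    outlier_shift: float = 20.0,
    noise: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Homography]:
    """Correspondence set with a known homography and planted gross outliers.

    Returns ``(xy_ref, xy_tgt, inlier_mask, H_true)``. Outliers are displaced
    by at least ``outlier_shift`` pixels in a random direction.
    """
    rng = np.random.default_rng(seed)
    if H is None:
        H = similarity_homography(rng.uniform(-0.4, 0.4), rng.uniform(0.9, 1.1),
                                  (extent / 2, extent / 2))
        H[0, 2] += rng.uniform(-10, 10)
        H[1, 2] += rng.uniform(-10, 10)
    Hm = Homography(H)
    xy_ref = rng.uniform(extent * 0.1, extent * 0.9, size=(n_inliers + n_outliers, 2))
    xy_tgt = Hm.apply(xy_ref)
    if noise > 0:
        xy_tgt = xy_tgt + rng.normal(0, noise, xy_tgt.shape)
    mask = np.ones(n_inliers + n_outliers, dtype=bool)
    out_idx = rng.choice(n_inliers + n_outliers, size=n_outliers, replace=False)
    mask[out_idx] = False
    ang = rng.uniform(0, 2 * np.pi, n_outliers)
    r = outlier_shift + rng.uniform(0, outlier_shift, n_outliers)
    xy_tgt[out_idx] += np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return xy_ref, xy_tgt, mask, Hm


# ------------------------------------------------------------ camera rigs

@dataclass
class RigFixture:
    """Planted 3-D points observed by 2–3 cameras on an arc."""

    points3d: np.ndarray  # (n, 3)
    cameras: list  # [(CameraIntrinsics, R, t)]
    observations: list  # [(n, 2) per camera], noise included
    exact_observations: list  # noise-free projections
    seed: int

    def relative_pose(self, i: int = 0, j: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """(R, t) of camera j in camera i's frame."""
        _, Ri, ti = self.cameras[i]
        _, Rj, tj = self.cameras[j]
        R = Rj @ Ri.T
        t = tj - R @ ti
        return R, t

    def essential(self, i: int = 0, j: int = 1) -> np.ndarray:
        R, t = self.relative_pose(i, j)
        tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
        return tx @ R

    def fundamental(self, i: int = 0, j: int = 1) -> np.ndarray:
        Ki = self.cameras[i][0].K
        Kj = self.cameras[j][0].K
        F = np.linalg.inv(Kj).T @ self.essential(i, j) @ np.linalg.inv(Ki)
        F = F / np.linalg.norm(F)
        return F if F[2, 2] >= 0 else -F


def _look_at(C: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pose (R, t) of a camera at center C looking at ``target`` (y down)."""
    z = target - C
    z = z / np.linalg.norm(z)
    up = np.array([0.0, -1.0, 0.0])  # world -y maps to image up (y grows down)
    x = np.cross(up, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    t = -R @ C
    return R, t


def make_rig(
    n_points: int = 100,
    n_cameras: int = 2,
    noise_sigma: float = 0.0,
    seed: int = 0,
    separation_deg: float = 11.5,
    image_size: int = 4096,
    focal: float = 6000.0,
) -> RigFixture:
    """Cameras on an arc observing a unit-diameter point cloud.

    Points fill a sphere of diameter 1 at the origin; cameras sit on an arc
    of radius 2 looking at the cloud center, so the default 11.5-degree
    separation gives a baseline of 0.4 and a depth of ~5 baselines. The
    camera emulates a modern ~12-megapixel sensor (4096 px wide, 6000 px
    focal — a normal lens), where 1 px of feature-localization noise is a
    realistic figure. Observations are exact projections plus seeded
    Gaussian noise of ``noise_sigma`` pixels.
    """
    if n_points < 20:
        raise ParameterError(f"n_points must be >= 20, got {n_points}")
    if n_cameras not in (2, 3):
        raise ParameterError(f"n_cameras must be 2 or 3, got {n_cameras}")
    if not 5.0 <= separation_deg <= 15.0:
        raise ParameterError("camera separation must be between 5 and 15 degrees")
    rng = np.random.default_rng(seed)
    # rejection-sample points inside the unit-diameter sphere
    pts = []
    while len(pts) < n_points:
        cand = rng.uniform(-0.5, 0.5, size=(n_points, 3))
        keep = np.linalg.norm(cand, axis=1) <= 0.5
        pts.extend(cand[keep].tolist())
    points3d = np.array(pts[:n_points])

    K = CameraIntrinsics(np.array([
        [focal, 0, image_size / 2.0],
        [0, focal, image_size / 2.0],
        [0, 0, 1.0],
    ]))
    D = 2.0
    cameras = []
    for i in range(n_cameras):
        phi = np.deg2rad((i - (n_cameras - 1) / 2.0) * separation_deg)
        C = D * np.array([np.sin(phi), 0.0, -np.cos(phi)])
        R, t = _look_at(C, np.zeros(3))
        cameras.append((K, R, t))

    exact = []
    for K_i, R, t in cameras:
        proj = reproject(projection_matrix(K_i, R, t), points3d)
        if np.any(proj < 0) or np.any(proj >= image_size):
            raise ParameterError("rig geometry projects points outside the frame")
        exact.append(proj)
    observations = [p + rng.normal(0, noise_sigma, p.shape) if noise_sigma > 0
                    else p.copy() for p in exact]
    return RigFixture(points3d=points3d, cameras=cameras,
                      observations=observations, exact_observations=exact,
                      seed=seed)


# -------------------------------------------- renderable two-plane scene

@dataclass
class PlaneSceneFixture:
    """A textured background plane plus a nearer foreground plane, rendered
    through 2–3 known cameras — planar-degeneracy-free imagery with an exact
    pixel-to-3-D ground-truth map."""

    images: list  # GrayImage per camera
    K: CameraIntrinsics
    cameras: list  # [(R, t)] per camera
    z_back: float
    z_front: float
    front_rect: tuple  # (x0, x1, y0, y1) world extent of the foreground plane
    diameter: float  # scene diameter (for error budgets)

    def backproject(self, cam_idx: int, xy: np.ndarray) -> np.ndarray:
        """True 3-D point seen at pixel(s) xy of camera ``cam_idx``."""
        R, t = self.cameras[cam_idx]
        C = -R.T @ t
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        rays = (R.T @ np.linalg.inv(self.K.K)
                @ np.hstack([xy, np.ones((xy.shape[0], 1))]).T).T
        out = np.empty((xy.shape[0], 3))
        for i, r in enumerate(rays):
            # try the nearer plane first; fall back to the background
            p = None
            if abs(r[2]) > 1e-12:
                s = (self.z_front - C[2]) / r[2]
                cand = C + s * r
                x0, x1, y0, y1 = self.front_rect
                if s > 0 and x0 <= cand[0] <= x1 and y0 <= cand[1] <= y1:
                    p = cand
                if p is None:
                    s = (self.z_back - C[2]) / r[2]
                    p = C + s * r
            out[i] = p if p is not None else np.nan
        return out


def _plane_homography(P: np.ndarray, origin: np.ndarray, ex: np.ndarray,
                      ey: np.ndarray) -> np.ndarray:
    """Texture (u, v) -> image (x, y) homography for plane X = origin + u ex + v ey."""
    M = np.column_stack([ex, ey, origin])
    return P @ np.vstack([M, [0.0, 0.0, 1.0]])


def make_two_plane_scene(
    seed: int = 0,
    n_cameras: int = 3,
    image_size: int = 560,
    focal: float = 750.0,
    separation_deg: float = 8.0,
) -> PlaneSceneFixture:
    """Render a plane-plus-relief scene: textured background at z=0.25 behind a
    textured foreground square at z=-0.25, viewed from cameras on an arc."""
    if n_cameras not in (2, 3):
        raise ParameterError("scene supports 2 or 3 cameras")
    K = CameraIntrinsics(np.array([
        [focal, 0, image_size / 2.0],
        [0, focal, image_size / 2.0],
        [0, 0, 1.0],
    ]))
    z_back, z_front = 0.25, -0.25
    # background spans 2x2 world units; foreground square 1x1. Texture
    # resolutions are chosen so a texel maps to roughly 1.5 image pixels,
    # keeping the fine texture bands visible after rendering.
    back_size, front_size = 512, 288
    back_origin = np.array([-1.0, -1.0, z_back])
    back_step = 2.0 / back_size
    front_origin = np.array([-0.5, -0.5, z_front])
    front_step = 1.0 / front_size
    tex_back = make_texture(back_size, back_size, seed=seed * 2 + 1,
                            style="multiband-noise")
    tex_front = make_texture(front_size, front_size, seed=seed * 2 + 2,
                             style="multiband-noise")

    D = 4.0
    cameras = []
    for i in range(n_cameras):
        phi = np.deg2rad((i - (n_cameras - 1) / 2.0) * separation_deg)
        C = D * np.array([np.sin(phi), 0.0, -np.cos(phi)])
        R, t = _look_at(C, np.zeros(3))
        cameras.append((R, t))

    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    images = []
    for R, t in cameras:
        P = projection_matrix(K, R, t)
        Hb = _plane_homography(P, back_origin, ex * back_step, ey * back_step)
        Hf = _plane_homography(P, front_origin, ex * front_step, ey * front_step)
        shape = (image_size, image_size)
        back_img = warp(tex_back.pixels, ProjectiveTransform(matrix=np.linalg.inv(Hb)),
                        output_shape=shape, order=1, cval=0.0, preserve_range=True)
        front_img = warp(tex_front.pixels, ProjectiveTransform(matrix=np.linalg.inv(Hf)),
                         output_shape=shape, order=1, cval=-1.0, preserve_range=True)
        composite = np.where(front_img >= 0, front_img, back_img)
        images.append(GrayImage(np.clip(composite, 0, 255)))

    return PlaneSceneFixture(
        images=images, K=K, cameras=cameras, z_back=z_back, z_front=z_front,
        front_rect=(-0.5, 0.5, -0.5, 0.5),
        diameter=float(np.linalg.norm([2.0, 2.0, z_back - z_front])),
    )
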