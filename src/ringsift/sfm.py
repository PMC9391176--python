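"""Two-view epipolar geometry and incremental sparse 3-D reconstruction.

The first image pair fixes the coordinate frame: the fundamental matrix F is
estimated by the normalized 8-point algorithm inside RANSAC (Sampson-distance
inliers), lifted to the essential matrix E = K'ᵀ F K, and decomposed by SVD
into the relative pose (R, T) — the candidate with the majority of
triangulated points in front of both cameras wins (cheirality). Projection
matrices P1 = K[I|0] and P2 = K[R|T] then triangulate every surviving
correspondence by linear DLT. A third view is registered against the second
image via 2-D–3-D correspondences (linear DLT PnP inside RANSAC) and adds
new tracks. The global scale is fixed by ||T|| = 1 for the first pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .errors import (InputError, LowParallaxError, ParameterError,
                     RansacFailureError, StageError)
from .image import GrayImage
from .robust import RansacConfig
from . import pipeline as pl


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    K: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K, dtype=np.float64)
        if K.shape != (3, 3):
            raise ParameterError(f"K must be 3x3, got {K.shape}")
        if abs(K[2, 2] - 1.0) > 1e-9 or abs(K[1, 0]) > 1e-9 or np.any(np.abs(K[2, :2]) > 1e-9):
            raise ParameterError("K must be upper-triangular with K[2,2] = 1")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ParameterError("focal entries of K must be positive")
        object.__setattr__(self, "K", K)

    @classmethod
    def from_file(cls, path) -> "CameraIntrinsics":
        """Read a 3x3 K from JSON (nested list or {"K": ...}) or 9 whitespace numbers."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"K file does not exist: {path}")
        text = path.read_text().strip()
        try:
            data = json.loads(text)
            if isinstance(data, dict):
                data = data["K"]
            K = np.asarray(data, dtype=float)
        except (json.JSONDecodeError, KeyError, ValueError):
            vals = [float(v) for v in text.split()]
            if len(vals) != 9:
                raise InputError(f"K file {path} must hold 9 numbers or a JSON 3x3 matrix")
            K = np.array(vals).reshape(3, 3)
        return cls(K.reshape(3, 3))

    @classmethod
    def approximate(cls, width: int, height: int) -> "CameraIntrinsics":
        """Fallback when no calibration is supplied: f = 1.2 * max dimension,
        principal point at the image center."""
        f = 1.2 * max(width, height)
        return cls(np.array([[f, 0, width / 2.0], [0, f, height / 2.0], [0, 0, 1]]))


@dataclass
class TwoViewGeometry:
    F: np.ndarray  # rank-2 fundamental matrix
    E: np.ndarray  # essential matrix, singular values (s, s, 0)
    R: np.ndarray  # relative rotation, det +1
    T_vec: np.ndarray  # unit translation direction
    P1: np.ndarray  # K [I | 0]
    P2: np.ndarray  # K'[R | T]


@dataclass
class PointCloud:
    points: np.ndarray  # (n, 3)
    colors: np.ndarray | None = None  # (n, 3) uint8
    tracks: list = dc_field(default_factory=list)  # per point: [(image id, kp id), ...]

    def __len__(self) -> int:
        return int(self.points.shape[0])


def _homogeneous(xy: np.ndarray) -> np.ndarray:
    xy = np.atleast_2d(xy)
    return np.hstack([xy, np.ones((xy.shape[0], 1))])


def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid at origin, mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    s = math.sqrt(2) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    return (pts - c) * s, T


def eight_point(xy_ref: np.ndarray, xy_tgt: np.ndarray) -> np.ndarray:
    """Normalized 8-point fundamental matrix (>= 8 correspondences), rank-2 enforced.

    Convention: ``x_tgtᵀ F x_ref = 0``.
    """
    xy_ref = np.asarray(xy_ref, dtype=float)
    xy_tgt = np.asarray(xy_tgt, dtype=float)
    if xy_ref.shape[0] < 8:
        raise ParameterError(f"8-point needs >= 8 correspondences, got {xy_ref.shape[0]}")
    n_ref, T1 = _normalize_2d(xy_ref)
    n_tgt, T2 = _normalize_2d(xy_tgt)
    x1, y1 = n_ref[:, 0], n_ref[:, 1]
    x2, y2 = n_tgt[:, 0], n_tgt[:, 1]
    A = np.column_stack([x2 * x1, x2 * y1, x2, y2 * x1, y2 * y1, y2, x1, y1,
                         np.ones_like(x1)])
    _, _, vt = np.linalg.svd(A)
    Fn = vt[-1].reshape(3, 3)
    U, S, Vt = np.linalg.svd(Fn)
    Fn = U @ np.diag([S[0], S[1], 0.0]) @ Vt
    F = T2.T @ Fn @ T1
    F = F / np.linalg.norm(F)
    if F[2, 2] < 0:
        F = -F
    return F


def sampson_distance(F: np.ndarray, xy_ref: np.ndarray, xy_tgt: np.ndarray) -> np.ndarray:
    """First-order geometric distance (pixels) to the epipolar constraint."""
    x1 = _homogeneous(xy_ref)
    x2 = _homogeneous(xy_tgt)
    Fx1 = x1 @ F.T  # rows: F x1
    Ftx2 = x2 @ F  # rows: F.T x2
    num = np.einsum("ij,ij->i", x2, Fx1)
    den = Fx1[:, 0] ** 2 + Fx1[:, 1] ** 2 + Ftx2[:, 0] ** 2 + Ftx2[:, 1] ** 2
    den = np.maximum(den, 1e-300)
    return np.abs(num) / np.sqrt(den)


def fundamental_8pt_ransac(
    xy_ref: np.ndarray,
    xy_tgt: np.ndarray,
    cfg: RansacConfig | None = None,
    sampson_threshold: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """RANSAC 8-point fundamental matrix. Returns (F, inlier mask)."""
    cfg = cfg or RansacConfig()
    xy_ref = np.asarray(xy_ref, dtype=float)
    xy_tgt = np.asarray(xy_tgt, dtype=float)
    n = xy_ref.shape[0]
    if n < 9:
        raise RansacFailureError(f"8-point RANSAC needs >= 9 correspondences, got {n}",
                                 reason="too few matches")
    rng = np.random.default_rng(cfg.seed)
    best_mask = None
    best_count = 0
    best_err = np.inf
    needed = cfg.max_iterations
    it = 0
    while it < min(needed, cfg.max_iterations):
        it += 1
        idx = rng.choice(n, size=8, replace=False)
        try:
            F = eight_point(xy_ref[idx], xy_tgt[idx])
        except (ParameterError, np.linalg.LinAlgError):
            continue
        d = sampson_distance(F, xy_ref, xy_tgt)
        mask = d < sampson_threshold
        count = int(mask.sum())
        err = float(d[mask].sum()) if count else np.inf
        if count > best_count or (count == best_count and err < best_err):
            best_mask, best_count, best_err = mask, count, err
            ratio = count / n
            if ratio > 0:
                denom = math.log(max(1 - ratio**8, 1e-12))
                needed = (1 if denom >= 0
                          else int(math.ceil(math.log(1 - cfg.confidence) / denom)))
    if best_mask is None or best_count < 9:
        raise RansacFailureError("no epipolar consensus found", reason="no consensus")
    # final refit on all inliers, then one reclassification
    F = eight_point(xy_ref[best_mask], xy_tgt[best_mask])
    d = sampson_distance(F, xy_ref, xy_tgt)
    mask = d < sampson_threshold
    if mask.sum() >= 8:
        F = eight_point(xy_ref[mask], xy_tgt[mask])
        mask = sampson_distance(F, xy_ref, xy_tgt) < sampson_threshold
    else:
        mask = best_mask
    return F, mask


def essential_from_f(F: np.ndarray, K_ref: CameraIntrinsics,
                     K_tgt: CameraIntrinsics) -> np.ndarray:
    """E = K_tgtᵀ F K_ref with singular values projected to (s, s, 0)."""
    E = K_tgt.K.T @ np.asarray(F, dtype=float) @ K_ref.K
    U, S, Vt = np.linalg.svd(E)
    s = (S[0] + S[1]) / 2.0
    return U @ np.diag([s, s, 0.0]) @ Vt


def essential_8pt(xy_ref: np.ndarray, xy_tgt: np.ndarray,
                  K_ref: CameraIntrinsics, K_tgt: CameraIntrinsics) -> np.ndarray:
    """Linear 8-point estimate of E directly in normalized image coordinates.

    The essential matrix has its special (s, s, 0) form only in the
    normalized camera system; fitting there (instead of projecting an
    uncalibrated F onto the essential manifold) keeps the epipolar residuals
    of the final pose small. Purely linear: least squares + singular-value
    projection.
    """
    xy_ref = np.atleast_2d(xy_ref)
    xy_tgt = np.atleast_2d(xy_tgt)
    if xy_ref.shape[0] < 8:
        raise ParameterError(f"8-point needs >= 8 correspondences, got {xy_ref.shape[0]}")
    x1 = _homogeneous(xy_ref) @ np.linalg.inv(K_ref.K).T
    x2 = _homogeneous(xy_tgt) @ np.linalg.inv(K_tgt.K).T
    A = np.column_stack([
        x2[:, 0] * x1[:, 0], x2[:, 0] * x1[:, 1], x2[:, 0],
        x2[:, 1] * x1[:, 0], x2[:, 1] * x1[:, 1], x2[:, 1],
        x1[:, 0], x1[:, 1], np.ones(len(x1)),
    ])
    _, _, vt = np.linalg.svd(A)
    E = vt[-1].reshape(3, 3)
    U, S, Vt = np.linalg.svd(E)
    s = (S[0] + S[1]) / 2.0
    return U @ np.diag([s, s, 0.0]) @ Vt


def projection_matrix(K: CameraIntrinsics, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return K.K @ np.hstack([R, np.asarray(t, dtype=float).reshape(3, 1)])


def triangulate(P1: np.ndarray, P2: np.ndarray, m: np.ndarray,
                m_prime: np.ndarray) -> np.ndarray:
    """Linear (DLT) triangulation of one correspondence. Returns inhomogeneous M.

    Raises LowParallaxError for an (effectively) zero baseline and
    ParameterError when the solution lies at infinity.
    """
    pts = triangulate_points(P1, P2, np.atleast_2d(m), np.atleast_2d(m_prime))
    M = pts[0]
    if not np.all(np.isfinite(M)):
        raise ParameterError("triangulated point at infinity (homogeneous w ~ 0)")
    return M


def triangulate_points(P1: np.ndarray, P2: np.ndarray, xy1: np.ndarray,
                       xy2: np.ndarray) -> np.ndarray:
    """Batch DLT triangulation; points at infinity come back as NaN rows."""
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    if P1.shape != (3, 4) or P2.shape != (3, 4):
        raise ParameterError("projection matrices must be 3x4")
    n1 = P1 / np.linalg.norm(P1)
    n2 = P2 / np.linalg.norm(P2)
    if np.linalg.norm(n1 - n2) < 1e-12 or np.linalg.norm(n1 + n2) < 1e-12:
        raise LowParallaxError("identical projection matrices: zero baseline")
    xy1 = np.atleast_2d(np.asarray(xy1, dtype=float))
    xy2 = np.atleast_2d(np.asarray(xy2, dtype=float))
    out = np.empty((xy1.shape[0], 3))
    for i in range(xy1.shape[0]):
        A = np.stack([
            xy1[i, 0] * P1[2] - P1[0],
            xy1[i, 1] * P1[2] - P1[1],
            xy2[i, 0] * P2[2] - P2[0],
            xy2[i, 1] * P2[2] - P2[1],
        ])
        _, _, vt = np.linalg.svd(A)
        Xh = vt[-1]
        if abs(Xh[3]) < 1e-12 * np.linalg.norm(Xh[:3]):
            out[i] = np.nan
        else:
            out[i] = Xh[:3] / Xh[3]
    return out


def reproject(P: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project (n, 3) world points through a 3x4 projection matrix."""
    X = np.atleast_2d(X)
    ph = (P @ np.hstack([X, np.ones((X.shape[0], 1))]).T).T
    return ph[:, :2] / ph[:, 2:3]


def _depths(R: np.ndarray, t: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-point depth (camera-frame z) for pose (R, t)."""
    X = np.atleast_2d(X)
    return (X @ R[2] + t[2])


def decompose_essential(
    E: np.ndarray,
    xy_ref: np.ndarray,
    xy_tgt: np.ndarray,
    K_ref: CameraIntrinsics,
    K_tgt: CameraIntrinsics,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover (R, unit T) from E by SVD + cheirality over the correspondences.

    All four candidate poses (U W Vᵀ / U Wᵀ Vᵀ, ±u3) are triangulated against
    the identity reference pose; the candidate with the most points at
    positive depth in *both* cameras wins.
    """
    U, _, Vt = np.linalg.svd(np.asarray(E, dtype=float))
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    candidates = []
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for t in (U[:, 2], -U[:, 2]):
            candidates.append((R, t / np.linalg.norm(t)))

    xy_ref = np.atleast_2d(xy_ref)
    xy_tgt = np.atleast_2d(xy_tgt)
    # subsample for speed; cheirality needs only a vote
    if xy_ref.shape[0] > 50:
        step = xy_ref.shape[0] // 50 + 1
        xy_ref, xy_tgt = xy_ref[::step], xy_tgt[::step]
    P1 = projection_matrix(K_ref, np.eye(3), np.zeros(3))
    best = None
    best_count = -1
    for R, t in candidates:
        P2 = projection_matrix(K_tgt, R, t)
        X = triangulate_points(P1, P2, xy_ref, xy_tgt)
        ok = np.all(np.isfinite(X), axis=1)
        d1 = X[ok, 2]
        d2 = _depths(R, t, X[ok])
        count = int(np.sum((d1 > 0) & (d2 > 0)))
        if count > best_count:
            best_count = count
            best = (R, t)
    if best is None or best_count <= 0:
        raise LowParallaxError("no essential-matrix pose places points in front of both cameras")
    return best


def two_view_geometry(
    xy_ref: np.ndarray,
    xy_tgt: np.ndarray,
    K_ref: CameraIntrinsics,
    K_tgt: CameraIntrinsics,
    cfg: RansacConfig | None = None,
    sampson_threshold: float = 2.0,
) -> tuple[TwoViewGeometry, np.ndarray]:
    """F -> E -> (R, T) -> projection matrices. Returns (geometry, inlier mask).

    E is first lifted from F (E = K'ᵀFK), then re-fit linearly on the inlier
    correspondences in normalized coordinates, where its (s, s, 0) structure
    actually lives — the projection of an uncalibrated F onto the essential
    manifold alone loses noticeable accuracy.
    """
    F, mask = fundamental_8pt_ransac(xy_ref, xy_tgt, cfg, sampson_threshold)
    E = essential_from_f(F, K_ref, K_tgt)
    if mask.sum() >= 8:
        E = essential_8pt(xy_ref[mask], xy_tgt[mask], K_ref, K_tgt)
    R, t = decompose_essential(E, xy_ref[mask], xy_tgt[mask], K_ref, K_tgt)
    P1 = projection_matrix(K_ref, np.eye(3), np.zeros(3))
    P2 = projection_matrix(K_tgt, R, t)
    geom = TwoViewGeometry(F=F, E=E, R=R, T_vec=t, P1=P1, P2=P2)
    return geom, mask


def pnp_dlt(X: np.ndarray, xy: np.ndarray,
            K: CameraIntrinsics) -> tuple[np.ndarray, np.ndarray]:
    """Linear DLT camera resection from >= 6 3-D–2-D correspondences.

    Works in normalized camera coordinates (K is known), then projects the
    linear estimate onto the nearest proper rotation. Returns (R, t).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    n = X.shape[0]
    if n < 6:
        raise ParameterError(f"DLT PnP needs >= 6 correspondences, got {n}")
    # normalized image coordinates: K^-1 x
    xn = (np.linalg.inv(K.K) @ _homogeneous(xy).T).T[:, :2]
    # condition the 3-D points
    c3 = X.mean(axis=0)
    s3 = math.sqrt(3) / max(np.linalg.norm(X - c3, axis=1).mean(), 1e-12)
    Xn = (X - c3) * s3

    A = np.zeros((2 * n, 12))
    for i in range(n):
        x, y, z = Xn[i]
        u, v = xn[i]
        A[2 * i] = [x, y, z, 1, 0, 0, 0, 0, -u * x, -u * y, -u * z, -u]
        A[2 * i + 1] = [0, 0, 0, 0, x, y, z, 1, -v * x, -v * y, -v * z, -v]
    _, _, vt = np.linalg.svd(A)
    Pn = vt[-1].reshape(3, 4)
    # undo the 3-D conditioning: X_cond = s3 * (X - c3)
    M = Pn[:, :3] * s3
    b = Pn[:, 3] - Pn[:, :3] @ (s3 * c3)
    # sign: centroid in front of the camera
    if (M[2] @ c3 + b[2]) < 0:
        M, b = -M, -b
    # nearest rotation to M; rescale t consistently
    U, S, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    scale = S.mean() if np.linalg.det(U @ Vt) > 0 else np.abs(S).mean()
    if scale <= 0:
        raise ParameterError("degenerate PnP system")
    t = b / scale
    return R, t


def pnp_ransac(
    X: np.ndarray,
    xy: np.ndarray,
    K: CameraIntrinsics,
    cfg: RansacConfig | None = None,
    reproj_threshold: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RANSAC DLT resection against known intrinsics. Returns (R, t, inlier mask)."""
    cfg = cfg or RansacConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    n = X.shape[0]
    if n < 7:
        raise RansacFailureError(f"PnP RANSAC needs >= 7 correspondences, got {n}",
                                 reason="too few matches")
    rng = np.random.default_rng(cfg.seed)
    best = None
    best_count = 0
    for _ in range(min(cfg.max_iterations, 500)):
        idx = rng.choice(n, size=6, replace=False)
        try:
            R, t = pnp_dlt(X[idx], xy[idx], K)
        except (ParameterError, np.linalg.LinAlgError):
            continue
        P = projection_matrix(K, R, t)
        err = np.linalg.norm(reproject(P, X) - xy, axis=1)
        mask = err < reproj_threshold
        count = int(mask.sum())
        if count > best_count:
            best_count = count
            best = mask
            if count == n:
                break
    if best is None or best_count < 6:
        raise RansacFailureError("no PnP consensus", reason="no consensus")
    R, t = pnp_dlt(X[best], xy[best], K)
    P = projection_matrix(K, R, t)
    mask = np.linalg.norm(reproject(P, X) - xy, axis=1) < reproj_threshold
    if mask.sum() >= 6:
        R, t = pnp_dlt(X[mask], xy[mask], K)
    else:
        mask = best
    return R, t, mask


def _filter_triangulated(X: np.ndarray, poses: list[tuple[np.ndarray, np.ndarray]],
                         obs: list[np.ndarray], K: CameraIntrinsics,
                         ceiling: float) -> np.ndarray:
    """Mask of points finite, in front of every camera, reprojecting within ceiling."""
    ok = np.all(np.isfinite(X), axis=1)
    for (R, t), xy in zip(poses, obs):
        P = projection_matrix(K, R, t)
        depth = _depths(R, t, X)
        with np.errstate(invalid="ignore"):
            err = np.linalg.norm(reproject(P, X) - xy, axis=1)
        ok &= (depth > 0) & (np.nan_to_num(err, nan=np.inf) < ceiling)
    return ok


@dataclass
class Reconstruction:
    cloud: PointCloud
    poses: list[dict]  # per image: {"R": 3x3 list, "t": 3 list}
    geometry: TwoViewGeometry
    report: dict


def reconstruct_from_tracks(
    observations: list[np.ndarray],
    K: CameraIntrinsics,
    cfg: RansacConfig | None = None,
    sampson_threshold: float = 2.0,
    reproj_ceiling: float = 2.0,
) -> Reconstruction:
    """Sparse reconstruction from pre-matched tracks across 2 or 3 views.

    ``observations[v]`` is an (n, 2) array: row ``i`` is point ``i`` seen in
    view ``v`` (all views observe the same indexed tracks). The first pair
    defines the frame (first camera at the origin, ||T|| = 1); a third view is
    registered by PnP on the points triangulated from the first pair, and the
    returned cloud keeps every track that survives the reprojection ceiling
    in all views it appears in.
    """
    cfg = cfg or RansacConfig()
    n_views = len(observations)
    if n_views not in (2, 3):
        raise ParameterError(f"reconstruction supports 2 or 3 views, got {n_views}")
    xy0, xy1 = observations[0], observations[1]
    if np.median(np.linalg.norm(xy0 - xy1, axis=1)) < 0.5:
        raise LowParallaxError("correspondences barely move between the views: "
                               "zero/near-zero baseline")
    geom, mask = two_view_geometry(xy0, xy1, K, K, cfg, sampson_threshold)
    idx = np.nonzero(mask)[0]
    X = triangulate_points(geom.P1, geom.P2, xy0[idx], xy1[idx])
    poses = [(np.eye(3), np.zeros(3)), (geom.R, geom.T_vec)]
    ok = _filter_triangulated(X, poses, [xy0[idx], xy1[idx]], K, reproj_ceiling)
    idx, X = idx[ok], X[ok]
    tracks = [[(0, int(i)), (1, int(i))] for i in idx]
    report = {"epipolar_inliers": int(mask.sum()),
              "triangulated_pair": int(X.shape[0])}

    if n_views == 3:
        xy2 = observations[2]
        R3, t3, pmask = pnp_ransac(X, xy2[idx], K, cfg, reproj_ceiling)
        poses.append((R3, t3))
        P3 = projection_matrix(K, R3, t3)
        err3 = np.linalg.norm(reproject(P3, X) - xy2[idx], axis=1)
        keep = err3 < reproj_ceiling
        for j in np.nonzero(keep)[0]:
            tracks[j].append((2, int(idx[j])))
        report["pnp_inliers"] = int(pmask.sum())

    cloud = PointCloud(points=X, tracks=tracks)
    pose_dicts = [{"R": R.tolist(), "t": np.asarray(t).tolist()} for R, t in poses]
    report["points"] = int(len(cloud))
    return Reconstruction(cloud=cloud, poses=pose_dicts, geometry=geom, report=report)


def reconstruct(
    images: list[GrayImage],
    K: CameraIntrinsics | None = None,
    config: PipelineConfig | None = None,
) -> Reconstruction:
    """Full image-based sparse reconstruction over 2 or 3 views.

    Runs the matching pipeline on the first pair, estimates the two-view
    geometry, triangulates, and (for 3 views) registers the third image by
    matching it against the second and resecting from already-triangulated
    points, then triangulates the new tracks it brings.

    The homography mismatch filter runs with a threshold of at least 2% of
    the image diagonal here: its job in reconstruction is removing gross
    mismatches, and the depth-induced parallax of a genuine 3-D scene
    (several pixels) must survive it — with the tight matching-stage
    threshold only the dominant scene plane would remain, which makes the
    fundamental matrix degenerate.
    """
    import dataclasses

    cfg = config or PipelineConfig()
    if len(images) not in (2, 3):
        raise ParameterError(f"reconstruction needs 2 or 3 images, got {len(images)}")
    approximate_k = K is None
    if K is None:
        K = CameraIntrinsics.approximate(images[0].width, images[0].height)
    diag = math.hypot(images[0].width, images[0].height)
    h_threshold = max(cfg.ransac_inlier_threshold, 0.02 * diag)
    match_cfg = dataclasses.replace(cfg, ransac_inlier_threshold=h_threshold)
    rcfg = RansacConfig(
        trim_fraction=cfg.trim_fraction, sample_size=cfg.ransac_sample_size,
        inlier_threshold=cfg.ransac_inlier_threshold,
        max_iterations=cfg.ransac_max_iterations,
        confidence=cfg.ransac_confidence, seed=cfg.seed,
    )

    feats = [pl.detect_and_describe(img, cfg) for img in images]
    res01 = pl.match_features(feats[0], feats[1], match_cfg)
    m01 = res01.inliers
    if len(m01) < 8:
        raise StageError("epipolar", RansacFailureError(
            f"only {len(m01)} matches survived filtering (need >= 8)",
            reason="too few matches"))
    if np.median(np.linalg.norm(m01.xy_ref - m01.xy_tgt, axis=1)) < 0.5:
        raise LowParallaxError("the two views are (nearly) identical: zero baseline")

    try:
        geom, mask = two_view_geometry(m01.xy_ref, m01.xy_tgt, K, K,
                                       rcfg, cfg.sampson_threshold)
    except RansacFailureError as exc:
        raise StageError("epipolar", exc) from exc
    idx = np.nonzero(mask)[0]
    X = triangulate_points(geom.P1, geom.P2, m01.xy_ref[idx], m01.xy_tgt[idx])
    poses = [(np.eye(3), np.zeros(3)), (geom.R, geom.T_vec)]
    ok = _filter_triangulated(X, poses, [m01.xy_ref[idx], m01.xy_tgt[idx]],
                              K, cfg.reproj_ceiling)
    idx, X = idx[ok], X[ok]
    # track bookkeeping: keypoint ids in images 0 and 1
    kp0 = [m01.pairs[i].index_ref for i in idx]
    kp1 = [m01.pairs[i].index_tgt for i in idx]
    tracks = [[(0, a), (1, b)] for a, b in zip(kp0, kp1)]
    points = [X]
    if X.shape[0]:
        e1 = np.linalg.norm(reproject(geom.P1, X) - m01.xy_ref[idx], axis=1)
        e2 = np.linalg.norm(reproject(geom.P2, X) - m01.xy_tgt[idx], axis=1)
        mean_reproj = float(np.mean(np.concatenate([e1, e2])))
    else:
        mean_reproj = None
    report = dict(res01.counts)
    report.update({"epipolar_inliers": int(mask.sum()),
                   "triangulated_pair": int(X.shape[0]),
                   "mean_reprojection_error": mean_reproj,
                   "approximate_k": approximate_k})

    if len(images) == 3:
        res12 = pl.match_features(feats[1], feats[2], match_cfg)
        m12 = res12.inliers
        # 2-D–3-D: image-1 keypoints that already have a 3-D point
        # key image-1 keypoints by position: orientation duplicates share a
        # location but not an index, and the detector ran once per image
        def poskey(x, y):
            return (round(x * 64), round(y * 64))

        kp1_to_row = {}
        for r, b in enumerate(kp1):
            k1 = feats[1].keypoints[b]
            kp1_to_row.setdefault(poskey(k1.x, k1.y), r)
        obj, img_pts, new_rows = [], [], []
        for r12, p in enumerate(m12.pairs):
            row = kp1_to_row.get(poskey(*m12.xy_ref[r12]))
            if row is not None:
                obj.append(X[row])
                img_pts.append(m12.xy_tgt[r12])
            else:
                new_rows.append(r12)
        if len(obj) < 7:
            raise StageError("pnp", RansacFailureError(
                f"only {len(obj)} 2-D–3-D correspondences for the third view",
                reason="too few matches"))
        try:
            R3, t3, pmask = pnp_ransac(np.array(obj), np.array(img_pts), K,
                                       rcfg, cfg.reproj_ceiling)
        except RansacFailureError as exc:
            raise StageError("pnp", exc) from exc
        poses.append((R3, t3))
        P2 = geom.P2
        P3 = projection_matrix(K, R3, t3)
        report["pnp_correspondences"] = len(obj)
        report["pnp_inliers"] = int(pmask.sum())

        # extend tracks of resected points with the third-view observation
        for r12, p in enumerate(m12.pairs):
            row = kp1_to_row.get(poskey(*m12.xy_ref[r12]))
            if row is not None:
                tracks[row].append((2, p.index_tgt))

        # triangulate brand-new tracks between views 1 and 2
        if new_rows:
            xy1n = m12.xy_ref[new_rows]
            xy2n = m12.xy_tgt[new_rows]
            Xn = triangulate_points(P2, P3, xy1n, xy2n)
            okn = _filter_triangulated(Xn, poses[1:], [xy1n, xy2n], K,
                                       cfg.reproj_ceiling)
            points.append(Xn[okn])
            for j in np.nonzero(okn)[0]:
                p = m12.pairs[new_rows[j]]
                tracks.append([(1, p.index_ref), (2, p.index_tgt)])
            report["triangulated_new"] = int(okn.sum())

    all_points = np.vstack(points) if points else np.empty((0, 3))
    # per-point gray intensity sampled from the first image observing it
    colors = np.zeros((all_points.shape[0], 3), dtype=np.uint8)
    for i, track in enumerate(tracks):
        img_id, kp_id = track[0]
        kp = feats[img_id].keypoints[kp_id]
        v = images[img_id].pixels[min(int(round(kp.y)), images[img_id].height - 1),
                                  min(int(round(kp.x)), images[img_id].width - 1)]
        colors[i] = int(round(v))
    cloud = PointCloud(points=all_points, colors=colors, tracks=tracks)
    report["points"] = int(len(cloud))
    pose_dicts = [{"R": R.tolist(), "t": np.asarray(t).tolist()} for R, t in poses]
    return Reconstruction(cloud=cloud, poses=pose_dicts, geometry=geom, report=report)
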