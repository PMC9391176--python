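"""Trimmed RANSAC mismatch removal.

Surviving matches are sorted by descriptor distance (best first); the worst
20% are dropped outright before any sampling, which raises the share of
correct pairs in the sampling pool and cuts the iteration count. RANSAC then
draws minimal 4-pair samples, fits a plane-projective homography by direct
linear transform, scores by symmetric transfer distance against a 2-pixel
threshold, and refits on the consensus set until the inlier set stops
changing.

A homography is an approximation for general 3-D scenes; it is used here as
a *filter* ahead of fundamental-matrix estimation, not as the final geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSampleError, ParameterError, RansacFailureError
from .matching import MatchSet


@dataclass(frozen=True)
class Homography:
    """A 3x3 plane-projective transform, normalized so H[2,2] = 1 when possible."""

    H: np.ndarray

    def __post_init__(self):
        H = np.asarray(self.H, dtype=np.float64)
        if H.shape != (3, 3):
            raise ParameterError(f"homography must be 3x3, got {H.shape}")
        if abs(np.linalg.det(H)) < 1e-12:
            raise ParameterError("homography is singular")
        if abs(H[2, 2]) > 1e-12:
            H = H / H[2, 2]
        else:
            H = H / np.linalg.norm(H)
        object.__setattr__(self, "H", H)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map (n, 2) points through the homography."""
        xy = np.atleast_2d(xy)
        ones = np.ones((xy.shape[0], 1))
        ph = (self.H @ np.hstack([xy, ones]).T).T
        return ph[:, :2] / ph[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H))


@dataclass(frozen=True)
class RansacConfig:
    trim_fraction: float = 0.2
    sample_size: int = 4
    inlier_threshold: float = 2.0  # pixels, per transfer direction
    max_iterations: int = 2000
    confidence: float = 0.995
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 1:
            raise ParameterError(f"trim_fraction must be in [0, 1), got {self.trim_fraction}")
        if self.sample_size < 4:
            raise ParameterError(f"sample_size must be >= 4, got {self.sample_size}")
        if self.inlier_threshold <= 0:
            raise ParameterError(f"inlier_threshold must be > 0, got {self.inlier_threshold}")


def trim_matches(matches: MatchSet, trim_fraction: float = 0.2) -> MatchSet:
    """Drop the worst ``floor(trim_fraction * N)`` pairs by descriptor distance.

    ``matches.pairs`` are already sorted best-first, so trimming removes the
    tail; ordering is preserved.
    """
    if not 0 <= trim_fraction < 1:
        raise ParameterError(f"trim_fraction must be in [0, 1), got {trim_fraction}")
    n = len(matches)
    n_drop = int(math.floor(trim_fraction * n))
    keep = np.arange(n - n_drop)
    matches.mark("trim", set(keep.tolist()))
    return matches.subset(keep)


def _collinear_triple(pts: np.ndarray, tol: float = 1e-8) -> bool:
    """True if any 3 of the points are (nearly) collinear."""
    n = pts.shape[0]
    scale = max(np.ptp(pts), 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                if abs(cross) < tol * scale * scale:
                    return True
    return False


def _dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform for >= 4 correspondences (unnormalized)."""
    n = src.shape[0]
    A = np.zeros((2 * n, 9))
    for i in range(n):
        x, y = src[i]
        u, v = dst[i]
        A[2 * i] = [-x, -y, -1, 0, 0, 0, u * x, u * y, u]
        A[2 * i + 1] = [0, 0, 0, -x, -y, -1, v * x, v * y, v]
    _, _, vt = np.linalg.svd(A)
    return vt[-1].reshape(3, 3)


def _normalize_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid 0, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = math.sqrt(2) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])
    normed = (pts - centroid) * s
    return normed, T


def fit_homography_minimal(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Exact homography from 4 correspondences (DLT on the minimal sample)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (4, 2) or dst.shape != (4, 2):
        raise ParameterError("minimal fit needs exactly 4 point pairs")
    if _collinear_triple(src) or _collinear_triple(dst):
        raise DegenerateSampleError("3 of the 4 sampled points are collinear")
    return Homography(_dlt_homography(src, dst))


def fit_homography_lsq(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Least-squares homography over >= 4 correspondences (normalized DLT)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape[0] < 4:
        raise ParameterError("least-squares fit needs >= 4 point pairs")
    ns, Ts = _normalize_points(src)
    nd, Td = _normalize_points(dst)
    Hn = _dlt_homography(ns, nd)
    return Homography(np.linalg.inv(Td) @ Hn @ Ts)


def symmetric_transfer_inliers(
    H: Homography, xy_ref: np.ndarray, xy_tgt: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inlier mask + per-pair max transfer error under forward & backward maps."""
    fwd = np.linalg.norm(H.apply(xy_ref) - xy_tgt, axis=1)
    bwd = np.linalg.norm(H.inverse().apply(xy_tgt) - xy_ref, axis=1)
    err = np.maximum(fwd, bwd)
    return err < threshold, err


def _adaptive_iterations(inlier_ratio: float, sample_size: int, confidence: float) -> int:
    if inlier_ratio <= 0:
        return 1 << 30
    denom = math.log(max(1.0 - inlier_ratio**sample_size, 1e-12))
    if denom >= 0:
        return 1
    return int(math.ceil(math.log(1.0 - confidence) / denom))


def ransac_refine(matches: MatchSet, cfg: RansacConfig) -> tuple[MatchSet, Homography]:
    """RANSAC + iterated least-squares refit on the trimmed match set.

    Raises :class:`RansacFailureError` with reason "too few matches" when
    fewer than ``sample_size + 1`` pairs are available, or "no consensus"
    when no model gathers ``sample_size + 1`` inliers.
    """
    n = len(matches)
    if n < cfg.sample_size + 1:
        raise RansacFailureError(
            f"need at least {cfg.sample_size + 1} pairs, got {n}", reason="too few matches"
        )
    rng = np.random.default_rng(cfg.seed)
    xy_ref, xy_tgt = matches.xy_ref, matches.xy_tgt

    best_mask: np.ndarray | None = None
    best_count = 0
    best_err = np.inf
    needed = cfg.max_iterations
    it = 0
    while it < min(needed, cfg.max_iterations):
        it += 1
        idx = rng.choice(n, size=cfg.sample_size, replace=False)
        try:
            H = fit_homography_minimal(xy_ref[idx][:4], xy_tgt[idx][:4])
        except (DegenerateSampleError, ParameterError):
            continue
        mask, err = symmetric_transfer_inliers(H, xy_ref, xy_tgt, cfg.inlier_threshold)
        count = int(mask.sum())
        total_err = float(err[mask].sum()) if count else np.inf
        if count > best_count or (count == best_count and total_err < best_err):
            best_mask, best_count, best_err = mask, count, total_err
            needed = _adaptive_iterations(count / n, cfg.sample_size, cfg.confidence)

    if best_mask is None or best_count < cfg.sample_size + 1:
        raise RansacFailureError(
            f"no model with >= {cfg.sample_size + 1} inliers after {it} iterations",
            reason="no consensus",
        )

    # refit-and-reclassify until the inlier set is stable
    mask = best_mask
    H = fit_homography_lsq(xy_ref[mask], xy_tgt[mask])
    for _ in range(20):
        new_mask, _ = symmetric_transfer_inliers(H, xy_ref, xy_tgt, cfg.inlier_threshold)
        if new_mask.sum() < cfg.sample_size:
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
        H = fit_homography_lsq(xy_ref[mask], xy_tgt[mask])

    keep = np.nonzero(mask)[0]
    matches.mark("ransac", set(keep.tolist()))
    return matches.subset(keep), H
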