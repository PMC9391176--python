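"""Initial matching (NNDR over arc-cosine similarity) and neighborhood voting.

Matching is exact nearest-neighbor search: because descriptors are unit
vectors, the angular distance ``arccos(<u, v>)`` orders candidates, and the
nearest/second-nearest distance ratio (NNDR) gates the initial match.

The voting filter then exploits geometric consistency: for a correct match,
the pattern of distances (and of main-direction differences) from its
reference keypoint to all other matched keypoints should look the same in
both images. Each candidate's two patterns are unit-normalized row vectors;
``dot1 = 1 - <distance rows>`` and ``dot2 = 1 - <orientation rows>`` are
dissimilarities in [0, 2], and a pair survives when ``dot1 < T_d`` and
``dot2 < T_theta`` (defaults 0.4 and 0.3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ParameterError
from .descriptor import Descriptor
from .keypoints import Keypoint

logger = logging.getLogger(__name__)

STAGES = ("nndr", "vote", "trim", "ransac")


@dataclass
class MatchPair:
    """One candidate correspondence between the two images' keypoint lists."""

    index_ref: int
    index_tgt: int
    desc_distance: float  # arccos similarity, radians in [0, pi]
    nndr: float  # nearest / second-nearest distance, in [0, 1]
    flags: dict = dc_field(default_factory=dict)  # per-stage survival


@dataclass
class MatchSet:
    """An ordered set of candidate pairs plus their keypoint coordinates.

    ``pairs`` stay sorted by ``desc_distance`` ascending (best first); the
    coordinate/orientation arrays are aligned with ``pairs`` so geometric
    filters need no access to the original keypoint lists.
    """

    pairs: list[MatchPair]
    xy_ref: np.ndarray  # (n, 2) reference-image coordinates
    xy_tgt: np.ndarray  # (n, 2) target-image coordinates
    theta_ref: np.ndarray  # (n,) main orientations
    theta_tgt: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, idx) -> "MatchSet":
        idx = np.asarray(idx, dtype=int)
        return MatchSet(
            pairs=[self.pairs[i] for i in idx],
            xy_ref=self.xy_ref[idx].reshape(-1, 2),
            xy_tgt=self.xy_tgt[idx].reshape(-1, 2),
            theta_ref=self.theta_ref[idx],
            theta_tgt=self.theta_tgt[idx],
        )

    def mark(self, stage: str, survivors: set[int]) -> None:
        for i, p in enumerate(self.pairs):
            p.flags[stage] = i in survivors


def wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    t = math.remainder(theta, 2.0 * math.pi)
    if t <= -math.pi:
        t += 2.0 * math.pi
    return t


def pair_geometry(kp_a: Keypoint, kp_b: Keypoint) -> tuple[float, float]:
    """Distance and wrapped main-direction difference of two same-image keypoints."""
    d = math.hypot(kp_b.x - kp_a.x, kp_b.y - kp_a.y)
    dtheta = wrap_angle((kp_b.main_theta or 0.0) - (kp_a.main_theta or 0.0))
    return d, dtheta


def nndr_match(
    desc_ref: list[Descriptor],
    desc_tgt: list[Descriptor],
    ratio_threshold: float = 0.8,
) -> MatchSet:
    """Initial matching by nearest-neighbor distance ratio over arccos distance.

    One-to-one: when several reference descriptors claim the same target, the
    smallest-distance claim wins. With fewer than two target descriptors no
    ratio exists; every nearest-neighbor pair passes with ``nndr = 0``.
    """
    if not desc_ref or not desc_tgt:
        raise ParameterError("descriptor lists must be non-empty")
    if not 0 < ratio_threshold <= 1:
        raise ParameterError(f"ratio_threshold must be in (0, 1], got {ratio_threshold}")

    ref_mat = np.stack([d.values for d in desc_ref])
    tgt_mat = np.stack([d.values for d in desc_tgt])
    sim = np.clip(ref_mat @ tgt_mat.T, -1.0, 1.0)
    dist = np.arccos(sim)

    candidates: list[tuple[int, int, float, float]] = []
    if dist.shape[1] < 2:
        logger.warning("fewer than 2 target descriptors: NNDR undefined, all pass")
        for i in range(dist.shape[0]):
            j = int(np.argmin(dist[i]))
            candidates.append((i, j, float(dist[i, j]), 0.0))
    else:
        order = np.argsort(dist, axis=1)
        for i in range(dist.shape[0]):
            j, j2 = order[i, 0], order[i, 1]
            d1, d2 = float(dist[i, j]), float(dist[i, j2])
            nndr = 0.0 if d1 == 0.0 else (1.0 if d2 == 0.0 else d1 / d2)
            if nndr < ratio_threshold:
                candidates.append((i, int(j), d1, nndr))

    # one-to-one on targets: keep the smallest-distance claim
    best_for_tgt: dict[int, tuple[int, int, float, float]] = {}
    for cand in candidates:
        j = cand[1]
        if j not in best_for_tgt or cand[2] < best_for_tgt[j][2]:
            best_for_tgt[j] = cand
    kept = sorted(best_for_tgt.values(), key=lambda c: c[2])

    pairs = [
        MatchPair(index_ref=i, index_tgt=j, desc_distance=d, nndr=r,
                  flags={"nndr": True})
        for i, j, d, r in kept
    ]
    kp_r = [desc_ref[p.index_ref].keypoint for p in pairs]
    kp_t = [desc_tgt[p.index_tgt].keypoint for p in pairs]
    return MatchSet(
        pairs=pairs,
        xy_ref=np.array([[k.x, k.y] for k in kp_r]).reshape(-1, 2),
        xy_tgt=np.array([[k.x, k.y] for k in kp_t]).reshape(-1, 2),
        theta_ref=np.array([k.main_theta for k in kp_r], dtype=float),
        theta_tgt=np.array([k.main_theta for k in kp_t], dtype=float),
    )


def _normalize_rows(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    out = np.divide(rows, norms, out=np.zeros_like(rows), where=norms > 0)
    return out


def vote_dissimilarities(matches: MatchSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (dot1, dot2): distance-row and orientation-row dissimilarities.

    For pair ``m``, the distance row holds the Euclidean distances from m's
    keypoint to every *other* matched keypoint in the same image; the
    orientation row holds the wrapped main-direction differences mapped to
    [0, 2pi). Both rows are unit-normalized and ``1 - inner product`` is
    returned. Rows that are identically zero in both images count as
    perfectly consistent (dissimilarity 0).
    """
    n = len(matches)
    dist_ref = np.linalg.norm(
        matches.xy_ref[:, None, :] - matches.xy_ref[None, :, :], axis=2)
    dist_tgt = np.linalg.norm(
        matches.xy_tgt[:, None, :] - matches.xy_tgt[None, :, :], axis=2)
    dth_ref = np.mod(matches.theta_ref[None, :] - matches.theta_ref[:, None]
                     + np.pi, 2 * np.pi) - np.pi  # wrapped to (-pi, pi]
    dth_tgt = np.mod(matches.theta_tgt[None, :] - matches.theta_tgt[:, None]
                     + np.pi, 2 * np.pi) - np.pi
    dth_ref = np.mod(dth_ref, 2 * np.pi)  # map to [0, 2pi) so rows are comparable
    dth_tgt = np.mod(dth_tgt, 2 * np.pi)

    off = ~np.eye(n, dtype=bool)
    d_ref = dist_ref[off].reshape(n, n - 1)
    d_tgt = dist_tgt[off].reshape(n, n - 1)
    t_ref = dth_ref[off].reshape(n, n - 1)
    t_tgt = dth_tgt[off].reshape(n, n - 1)

    def dissim(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        inner = np.einsum("ij,ij->i", _normalize_rows(a), _normalize_rows(b))
        out = 1.0 - inner
        both_zero = (na == 0) & (nb == 0)
        one_zero = (na == 0) ^ (nb == 0)
        out[both_zero] = 0.0
        out[one_zero] = 1.0
        return out

    return dissim(d_ref, d_tgt), dissim(t_ref, t_tgt)


def vote_filter(
    matches: MatchSet,
    T_theta: float = 0.3,
    T_d: float = 0.4,
) -> MatchSet:
    """Keep pairs whose neighborhood geometry agrees across the two images.

    A pair survives when both its distance-row dissimilarity (< ``T_d``) and
    orientation-row dissimilarity (< ``T_theta``) are small. Sets of two or
    fewer pairs have no neighborhood to vote with and pass unfiltered.
    """
    n = len(matches)
    if n <= 2:
        logger.warning("vote_filter: %d pair(s) — too few to vote, passing through", n)
        matches.mark("vote", set(range(n)))
        return matches.subset(np.arange(n))
    dot1, dot2 = vote_dissimilarities(matches)
    keep = np.nonzero((dot1 < T_d) & (dot2 < T_theta))[0]
    matches.mark("vote", set(keep.tolist()))
    return matches.subset(keep)
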