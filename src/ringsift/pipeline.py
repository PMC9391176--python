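"""End-to-end drivers: preprocess -> detect -> describe -> match -> filter.

These functions glue the per-stage modules together for the CLI and the SFM
reconstructor, returning per-stage results so reports can show how many
pairs each filter kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import gradients, keypoints as kpmod, matching, robust
from .config import PipelineConfig
from .descriptor import Descriptor, build_descriptor
from .errors import StageError
from .image import GrayImage, median_filter
from .keypoints import Keypoint
from .matching import MatchSet
from .robust import Homography, RansacConfig

logger = logging.getLogger(__name__)


@dataclass
class Features:
    """Keypoints (one orientation each) with their descriptors for one image."""

    keypoints: list[Keypoint]
    descriptors: list[Descriptor]

    def __len__(self) -> int:
        return len(self.descriptors)


@dataclass
class MatchResult:
    """Stage-by-stage matching outcome for one image pair."""

    initial: MatchSet  # after NNDR
    voted: MatchSet
    trimmed: MatchSet
    inliers: MatchSet  # after RANSAC
    homography: Homography
    counts: dict = dc_field(default_factory=dict)


def detect_and_describe(img: GrayImage, config: PipelineConfig | None = None) -> Features:
    """Run preprocessing, detection, orientation, and description on one image."""
    cfg = config or PipelineConfig()
    img = median_filter(img, cfg.median_window)
    ss = kpmod.build_scale_space(
        img, octaves=cfg.octaves, layers_per_octave=cfg.layers_per_octave,
        base_sigma=cfg.base_sigma,
    )
    kps = kpmod.detect_extrema(ss, cfg.contrast_threshold, cfg.edge_ratio)

    # gradient fields per (octave, layer), computed lazily
    cache: dict[tuple[int, int], gradients.GradientField] = {}

    def field_for(kp: Keypoint) -> gradients.GradientField:
        key = (kp.octave, kp.layer)
        if key not in cache:
            layer = ss.gaussians[kp.octave][kp.layer]
            first = gradients.first_order_field(layer, ss.layer_sigma(kp.layer))
            cache[key] = (gradients.second_order_field(first)
                          if cfg.descriptor_field == "second" else first)
        return cache[key]

    oriented = [k for kp in kps if (k := kpmod.assign_orientations(kp, field_for(kp)))]
    expanded = kpmod.expand_orientations(oriented)

    out_kps: list[Keypoint] = []
    descs: list[Descriptor] = []
    for kp in expanded:
        desc = build_descriptor(kp, field_for(kp), cfg.radius_per_ring,
                                cfg.scale_with_sigma)
        if desc is not None:
            out_kps.append(kp)
            descs.append(desc)
    logger.info("detected %d keypoints, %d descriptors", len(kps), len(descs))
    return Features(keypoints=out_kps, descriptors=descs)


def match_features(feat_ref: Features, feat_tgt: Features,
                   config: PipelineConfig | None = None) -> MatchResult:
    """NNDR match then vote, trim, and RANSAC filtering between two images."""
    cfg = config or PipelineConfig()
    try:
        initial = matching.nndr_match(feat_ref.descriptors, feat_tgt.descriptors,
                                      cfg.nndr_ratio)
    except Exception as exc:
        raise StageError("nndr", exc) from exc
    try:
        voted = matching.vote_filter(initial, T_theta=cfg.T_theta, T_d=cfg.T_d)
    except Exception as exc:
        raise StageError("vote", exc) from exc
    try:
        trimmed = robust.trim_matches(voted, cfg.trim_fraction)
    except Exception as exc:
        raise StageError("trim", exc) from exc
    rcfg = RansacConfig(
        trim_fraction=cfg.trim_fraction,
        sample_size=cfg.ransac_sample_size,
        inlier_threshold=cfg.ransac_inlier_threshold,
        max_iterations=cfg.ransac_max_iterations,
        confidence=cfg.ransac_confidence,
        seed=cfg.seed,
    )
    try:
        inliers, H = robust.ransac_refine(trimmed, rcfg)
    except Exception as exc:
        raise StageError("ransac", exc) from exc
    counts = {"nndr": len(initial), "vote": len(voted),
              "trim": len(trimmed), "ransac": len(inliers)}
    return MatchResult(initial=initial, voted=voted, trimmed=trimmed,
                       inliers=inliers, homography=H, counts=counts)


def match_images(img_a: GrayImage, img_b: GrayImage,
                 config: PipelineConfig | None = None
                 ) -> tuple[Features, Features, MatchResult]:
    """Full two-image pipeline from raw grayscale grids to RANSAC inliers."""
    cfg = config or PipelineConfig()
    feat_a = detect_and_describe(img_a, cfg)
    feat_b = detect_and_describe(img_b, cfg)
    return feat_a, feat_b, match_features(feat_a, feat_b, cfg)


def correct_match_mask(matches: MatchSet, H_true, tol: float = 2.0) -> np.ndarray:
    """Ground-truth check: a pair is correct iff ||H_true . ref - tgt|| <= tol px."""
    if not isinstance(H_true, Homography):
        H_true = Homography(np.asarray(H_true, dtype=float))
    if len(matches) == 0:
        return np.zeros(0, dtype=bool)
    pred = H_true.apply(matches.xy_ref)
    return np.linalg.norm(pred - matches.xy_tgt, axis=1) <= tol
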