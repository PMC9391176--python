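"""Pipeline configuration: every tunable with its default, validated on load."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """All tunables of the matching + reconstruction pipeline.

    Defaults encode the method's printed constants: 8 rings x 8 bins = 64-dim
    descriptor, voting thresholds T_theta=0.3 / T_d=0.4, 20% trim, 4-pair
    RANSAC samples with a 2-pixel inlier threshold.
    """

    # preprocessing
    median_window: int = 3
    # detection (classical SIFT defaults)
    octaves: int | None = None  # None -> derived from image size
    layers_per_octave: int = 3
    base_sigma: float = 1.6
    contrast_threshold: float = 0.03
    edge_ratio: float = 10.0
    # descriptor (ring/bin counts are structural: 8 x 8 = 64 dimensions)
    n_rings: int = 8
    n_bins: int = 8
    radius_per_ring: float = 1.0
    scale_with_sigma: bool = True
    descriptor_field: str = "second"  # "second" (re-differentiated) or "first"
    # matching
    nndr_ratio: float = 0.8
    T_theta: float = 0.3
    T_d: float = 0.4
    # robust filtering
    trim_fraction: float = 0.2
    ransac_sample_size: int = 4
    ransac_inlier_threshold: float = 2.0
    ransac_max_iterations: int = 2000
    ransac_confidence: float = 0.995
    # epipolar stage
    sampson_threshold: float = 2.0
    reproj_ceiling: float = 2.0
    # randomness
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        def check(cond: bool, field: str, rule: str):
            if not cond:
                raise ParameterError(f"config field '{field}' invalid: {rule} "
                                     f"(got {getattr(self, field)!r})")

        check(self.median_window >= 3 and self.median_window % 2 == 1,
              "median_window", "must be odd and >= 3")
        check(self.octaves is None or self.octaves >= 1, "octaves", "must be >= 1 or null")
        check(self.layers_per_octave >= 3, "layers_per_octave", "must be >= 3")
        check(self.base_sigma > 0, "base_sigma", "must be > 0")
        check(self.contrast_threshold > 0, "contrast_threshold", "must be > 0")
        check(self.edge_ratio > 1, "edge_ratio", "must be > 1")
        check(self.n_rings == 8, "n_rings", "descriptor layout is fixed at 8 rings")
        check(self.n_bins == 8, "n_bins", "descriptor layout is fixed at 8 bins")
        check(self.radius_per_ring > 0, "radius_per_ring", "must be > 0")
        check(self.descriptor_field in ("first", "second"),
              "descriptor_field", "must be 'first' or 'second'")
        check(0 < self.nndr_ratio <= 1, "nndr_ratio", "must be in (0, 1]")
        check(self.T_theta > 0, "T_theta", "must be > 0")
        check(self.T_d > 0, "T_d", "must be > 0")
        check(0 <= self.trim_fraction < 1, "trim_fraction", "must be in [0, 1)")
        check(self.ransac_sample_size >= 4, "ransac_sample_size", "must be >= 4")
        check(self.ransac_inlier_threshold > 0, "ransac_inlier_threshold", "must be > 0")
        check(self.ransac_max_iterations >= 1, "ransac_max_iterations", "must be >= 1")
        check(0 < self.ransac_confidence < 1, "ransac_confidence", "must be in (0, 1)")
        check(self.sampson_threshold > 0, "sampson_threshold", "must be > 0")
        check(self.reproj_ceiling > 0, "reproj_ceiling", "must be > 0")
        check(isinstance(self.seed, int) and self.seed >= 0, "seed", "must be a non-negative integer")

    @property
    def descriptor_dim(self) -> int:
        return self.n_rings * self.n_bins

    @classmethod
    def from_file(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        """Load YAML (JSON is a subset of YAML) with optional flag overrides."""
        path = Path(path)
        if not path.exists():
            raise ParameterError(f"config file does not exist: {path}")
        try:
            data = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError:
            data = json.loads(path.read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config field(s): {sorted(unknown)}")
        if overrides:
            data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
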