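"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional, Tuple

import yaml

from .dog import DogParams
from .localize import AnisotropyScale
from .ransac import RansacParams

RANSAC_MODES = ("off", "single", "multi")
INTENSITY_MODES = ("interpolate", "gauss_refit")
BACKGROUND_MODES = ("none", "plane")


@dataclass(frozen=True)
class RunConfig:
    """All detection parameters with their defaults.

    sigma/dog_k/threshold : DoG seeding (spot scale and intensity)
    support_radius : gradient patch radius r; (2r+1)^n pixels, (2r)^n gradients
    background : local background correction of each patch
    anisotropy : global axial scale factor a (sigma_z = sigma/a)
    ransac : "off" (all gradients), "single", or "multi" (close-pair separation)
    epsilon : RANSAC inlier distance in scaled pixels
    min_inliers : minimum consensus size
    weight_scheme : gradient weighting in the least-squares fit
    intensity : "interpolate" or "gauss_refit"
    min_separation : redundancy-filter distance in pixels
    block_size : per-axis block extents for block-wise processing
    seed : global RNG seed; per-candidate seeds derive from it
    """

    sigma: float = 1.5
    dog_k: float = 1.6
    threshold: float = 0.007
    support_radius: int = 3
    background: str = "none"
    anisotropy: float = 1.0
    ransac: str = "single"
    epsilon: float = 0.5
    min_inliers: int = 30
    max_iterations: int = 1000
    confidence: float = 0.99
    weight_scheme: str = "magnitude2"
    intensity: str = "interpolate"
    min_separation: float = 0.5
    block_size: Tuple[int, ...] = (256, 256, 128)
    seed: int = 42

    def __post_init__(self):
        if self.ransac not in RANSAC_MODES:
            raise ValueError(f"ransac must be one of {RANSAC_MODES}")
        if self.intensity not in INTENSITY_MODES:
            raise ValueError(f"intensity must be one of {INTENSITY_MODES}")
        if self.background not in BACKGROUND_MODES:
            raise ValueError(f"background must be one of {BACKGROUND_MODES}")
        if self.support_radius < 1:
            raise ValueError("support_radius must be >= 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        DogParams(sigma=self.sigma, k=self.dog_k, threshold=self.threshold,
                  anisotropy=self.anisotropy)
        RansacParams(epsilon=self.epsilon, min_inliers=self.min_inliers,
                     max_iterations=self.max_iterations,
                     confidence=self.confidence)

    def dog_params(self) -> DogParams:
        return DogParams(sigma=self.sigma, k=self.dog_k,
                         threshold=self.threshold, anisotropy=self.anisotropy)

    def ransac_params(self, rng_seed: int = 0) -> RansacParams:
        return RansacParams(epsilon=self.epsilon, min_inliers=self.min_inliers,
                            max_iterations=self.max_iterations,
                            confidence=self.confidence,
                            multi_consensus=self.ransac == "multi",
                            rng_seed=rng_seed,
                            weight_scheme=self.weight_scheme)

    def scale(self) -> AnisotropyScale:
        return AnisotropyScale(self.anisotropy)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_size"] = list(self.block_size)
        return d


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    values = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "block_size" in values and values["block_size"] is not None:
        bs = values["block_size"]
        if isinstance(bs, str):
            bs = [int(v) for v in bs.split(",")]
        values["block_size"] = tuple(int(v) for v in bs)
    return RunConfig(**values)
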