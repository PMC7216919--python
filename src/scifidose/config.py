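"""Pipeline configuration: defaults, YAML round-trip, provenance hashing.

The defaults reproduce the reference measurement-chain parameters exactly:
3x3 median filter, 5x5 binning, 200 µm profile sampling with n = 123 samples
(24.6 mm support), disk radii R_j = 0.4 + 0.2*j mm for j = 1..122
(0.6–24.8 mm), 7000 SIRT iterations from beta = 0, disk-stack ("dose")
profile for metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

from .phantom import CameraSpec, DetectorGeometry

__all__ = [
    "PreprocessConfig",
    "ReconstructionConfig",
    "MetricsConfig",
    "PipelineConfig",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    median_filter: bool = True
    bin_factor: int = 5
    background_fraction: float = 0.1
    target_spacing: float = 0.2  # mm


@dataclass(frozen=True)
class ReconstructionConfig:
    n_samples: int = 123
    r0: float = 0.4  # mm, recurrence seed of the disk radii
    dr: float = 0.2  # mm, radius step
    m_disks: int = 122
    n_iter: int = 7000
    profile_kind: str = "dose"  # or "reprojection"


@dataclass(frozen=True)
class MetricsConfig:
    center_threshold: float = 0.05
    reference_field: str = "cone15"


@dataclass(frozen=True)
class PipelineConfig:
    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    camera: CameraSpec = field(default_factory=CameraSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, block):
            block = dict(block or {})
            if klass is CameraSpec and "fov_x" in block:
                block["fov_x"] = tuple(block["fov_x"])
            return klass(**block)

        return cls(
            geometry=build(DetectorGeometry, data.get("geometry")),
            camera=build(CameraSpec, data.get("camera")),
            preprocess=build(PreprocessConfig, data.get("preprocess")),
            reconstruction=build(ReconstructionConfig, data.get("reconstruction")),
            metrics=build(MetricsConfig, data.get("metrics")),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def hash(self) -> str:
        """Stable digest of the fully resolved configuration, for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def log_effective(self) -> None:
        logger.info("effective pipeline configuration: %s", self.to_dict())
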