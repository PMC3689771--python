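"""Pipeline configuration and single-volume orchestration.

A :class:`PipelineConfig` gathers every knob of the workflow -- normalization
percentiles, transform parameters, stage thresholds, minIP geometry,
evaluation settings and the named A/B/C screening presets -- so a run is
fully reproducible from one flat, human-editable YAML document plus the
input volumes.  The presets ship with site-calibrated defaults chosen on the
standard phantom cohort's FROC frontier (moderate / good / high
sensitivity); on real data they should be re-calibrated the same way.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .detect import Candidate, DetectionParams, find_candidates
from .io import VoxelVolume
from .minip import MinIPSpec, filter_candidates
from .normalize import NormalizationSpec, range_normalize
from .rst import RSTParams, rst

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_PRESETS"]

# (t3d, t2d) pairs on the standard phantom cohort's frontier:
# A = moderate, B = good, C = high sensitivity.  Site-calibrated values.
DEFAULT_PRESETS: dict[str, tuple[float, float]] = {
    "A": (3.0, 2.0),
    "B": (3.0, 1.0),
    "C": (0.5, 0.5),
}


@dataclass(frozen=True)
class PipelineConfig:
    """All settings of a detection run."""

    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    rst: RSTParams = field(default_factory=RSTParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    minip: MinIPSpec = field(default_factory=MinIPSpec)
    tol_mm: float = 5.0
    scope: str = "all"
    presets: dict = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    seed: int = 0

    def __post_init__(self) -> None:
        a3, a2 = self.presets["A"]
        c3, c2 = self.presets["C"]
        if a3 < c3 or a2 < c2:
            raise ValueError(
                "preset A must be at least as strict as preset C on both thresholds"
            )

    def with_thresholds(self, t3d: float, t2d: float) -> "PipelineConfig":
        from dataclasses import replace

        return replace(
            self,
            detection=DetectionParams(
                t3d=t3d, t2d=t2d, connectivity=self.detection.connectivity
            ),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["presets"] = {k: list(v) for k, v in self.presets.items()}
        return d

    def config_hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        if "normalization" in raw:
            kwargs["normalization"] = NormalizationSpec(**raw["normalization"])
        if "rst" in raw:
            r = dict(raw["rst"])
            if "radii_mm" in r:
                r["radii_mm"] = tuple(r["radii_mm"])
            kwargs["rst"] = RSTParams(**r)
        if "detection" in raw:
            kwargs["detection"] = DetectionParams(**raw["detection"])
        if "minip" in raw:
            kwargs["minip"] = MinIPSpec(**raw["minip"])
        for key in ("tol_mm", "scope", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "presets" in raw:
            kwargs["presets"] = {
                k: tuple(v) for k, v in raw["presets"].items()
            }
        return cls(**kwargs)


def run_pipeline(
    volume: VoxelVolume, mask: VoxelVolume, config: PipelineConfig = PipelineConfig()
) -> tuple[list[Candidate], dict]:
    """Run normalize -> 3D RST -> stage-1 detection -> minIP stage 2.

    Returns all candidates (statuses set) and a stage-count summary dict.
    """
    normalized = range_normalize(volume, mask, config.normalization)
    symmetry = rst(normalized, config.rst)
    stage1 = find_candidates(symmetry, mask, config.detection, volume=normalized)
    final = filter_candidates(
        normalized, stage1, config.rst, config.minip, config.detection.t2d
    )
    counts = {
        "stage1": len(stage1),
        "passed_2d": sum(1 for c in final if c.status == "passed_2d"),
        "rejected_2d": sum(1 for c in final if c.status == "rejected_2d"),
    }
    return final, counts
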