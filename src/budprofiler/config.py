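"""Pipeline configuration: validated, serializable, hashable.

Unknown keys are rejected by name so a typo in a YAML file cannot silently
fall back to a default; the SHA-256 of the canonical JSON form is stamped
into every output table for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import GfpPatternSpec

__all__ = ["PipelineConfig", "UnknownConfigKeyError"]

SCHEMA_ID = "budprofiler-pipeline-v1"


class UnknownConfigKeyError(ValueError):
    """A configuration mapping contained a key the schema does not define."""


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, with documented defaults."""

    schema: str = SCHEMA_ID
    seed: int = 0
    # scene generation
    scene: dict = field(default_factory=dict)  # SceneConfig overrides
    proteins: dict = field(default_factory=dict)  # name -> GfpPatternSpec kwargs
    images_per_protein: int = 2
    # segmentation / geometry
    contour_thickness: float = 5.0
    robust_sigma: float = 5.0
    mean_cell_radius: float = 15.0
    axis_ratio_min: float = 0.7  # yeast cells are nearly round
    # confidence
    min_cell_area: int = 50
    min_cell_axis: float = 3.0
    n_size_bins: int = 7
    # features
    rfp_model_min_cells: int = 100
    # time profiles
    stage_exponent: float = 1.5
    bandwidth: float = 1700.0
    n_keypoints: int = 10
    # clustering / enrichment
    cluster_metric: str = "ml"
    enrichment_n_perm: int = 200
    match_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.cluster_metric not in ("ml", "euclidean", "correlation"):
            raise ValueError(f"unknown cluster metric {self.cluster_metric!r}")
        known_scene = {f.name for f in dataclasses.fields(__import__(
            "budprofiler.synthetic", fromlist=["SceneConfig"]
        ).SceneConfig)}
        unknown = set(self.scene) - known_scene
        if unknown:
            raise UnknownConfigKeyError(f"unknown scene keys: {sorted(unknown)}")
        for name, spec in self.proteins.items():
            if isinstance(spec, dict):
                known = {f.name for f in dataclasses.fields(GfpPatternSpec)}
                bad = set(spec) - known
                if bad:
                    raise UnknownConfigKeyError(
                        f"unknown pattern keys for {name!r}: {sorted(bad)}"
                    )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise UnknownConfigKeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
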