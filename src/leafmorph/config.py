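"""Pipeline configuration: schema-validated JSON, unknown keys rejected."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["SegmentedImageConfig", "ProfileImageConfig", "StatsConfig", "PipelineConfig"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentedImageConfig(_StrictModel):
    """One segmented epidermis micrograph."""

    path: str
    scale_um_per_px: float = Field(gt=0)
    species: str
    side: str  # "ab" | "ad"
    image_id: str | None = None

    @field_validator("side")
    @classmethod
    def _side(cls, v: str) -> str:
        if v not in ("ab", "ad"):
            raise ValueError("side must be 'ab' or 'ad'")
        return v


class ProfileImageConfig(_StrictModel):
    """One fold-line trichome profile micrograph."""

    path: str
    scale_um_per_px: float = Field(gt=0)
    species: str
    edge_length_mm: float = Field(gt=0)
    opening_radius_um: float = Field(default=15.0, gt=0)
    image_id: str | None = None


class StatsConfig(_StrictModel):
    correlation_level: str = "image"  # cell | image | species
    standardize: bool = True
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    n_cluster_groups: int = 2


class PipelineConfig(_StrictModel):
    """Whole-run configuration, serialized as one JSON file."""

    segmented_images: list[SegmentedImageConfig] = Field(default_factory=list)
    profile_images: list[ProfileImageConfig] = Field(default_factory=list)
    palette_file: str | None = None
    outline_threshold: float | str = "otsu"
    guard_cell_pairing: int = 2
    include_border_cells: bool = False
    perimeter_method: str = "edges"
    stats: StatsConfig = Field(default_factory=StatsConfig)
    seed: int = 0
    out_dir: str = "leafmorph_run"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2)
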