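"""Run configuration: one schema-versioned YAML document drives the whole
pipeline. Unknown keys are rejected so typos fail loudly."""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SeedConfig(_Strict):
    synth: int = 0
    train: int = 0
    infiltrate_train: int = 1


class SynthConfig(_Strict):
    width: int = 1024
    height: int = 1024
    tumour_ki67: float = 0.15
    with_infiltrate: bool = True
    mask_downsample: int = 8


class ExtractConfig(_Strict):
    patch_size: int = 64
    stride: int = 64
    purity: float = 0.9
    mi_threshold: float = 235.0
    augmentations: list[str] = Field(default_factory=list)
    max_patches: int = 2000
    holdout_fraction: float = 0.2


class TrainConfig(_Strict):
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 15
    batch_size: int = 25
    dropout_rate: float = 0.5
    infiltrate_epochs: int = 4
    infiltrate_max_patches: int = 600


class InferConfig(_Strict):
    stride: int = 32
    infiltrate_threshold: float = 0.5
    binarise_threshold: float = 0.55
    colour_edges: list[float] = Field(default_factory=lambda: [0.55, 0.65, 0.75])


class HotspotConfig(_Strict):
    od_threshold: float = 0.15
    min_area_px: int = 20
    morph_radius: int = 1
    ra: float = 200.0
    diameter_px: float = 100.0
    ratio_threshold: float = 0.20
    bands: list[float] = Field(default_factory=list)


class ValidateConfig(_Strict):
    downsample: int = 8
    tissue_only: bool = True


class PathsConfig(_Strict):
    slide: str | None = None
    annotations: str | None = None
    model: str | None = None
    infiltrate_model: str | None = None


class RunConfig(_Strict):
    schema_version: int = 1
    seeds: SeedConfig = Field(default_factory=SeedConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    extract: ExtractConfig = Field(default_factory=ExtractConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    infer: InferConfig = Field(default_factory=InferConfig)
    hotspot: HotspotConfig = Field(default_factory=HotspotConfig)
    validate_cfg: ValidateConfig = Field(default_factory=ValidateConfig, alias="validate")
    paths: PathsConfig = Field(default_factory=PathsConfig)

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(
            self.model_dump(by_alias=True), sort_keys=True, default_flow_style=False
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
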