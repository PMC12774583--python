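"""Pipeline configuration: YAML schema, validation and defaults.

Unknown keys are rejected by name; range and type problems are reported
all at once (pydantic collects every error). Paths are resolved relative
to the config file's directory.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .synth import SynthConfig


class ConfigError(ValueError):
    pass


class TrackConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    path: str
    format: str                       # bedgraph | wig | bed | tsv | vcf-info
    kind: str                         # numeric | categorical
    value_column: Optional[str] = None
    info_field: Optional[str] = None


class FeatureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    source: str
    kind: str
    imputation: str = "indicator"
    fixed_value: Optional[float] = None
    levels: list[str] = []


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    l2: float = Field(0.1, gt=0.0)
    max_iter: int = Field(100, ge=1)
    standardize: bool = False


class SubsetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    feature: str
    values: list[str]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    reference: str
    maf: str
    ref_species: str
    out_dir: str
    ancestor_label: Optional[str] = None
    outgroup_labels: Optional[list[str]] = None
    consensus_strategy: str = "strict_consensus"
    population_vcf: Optional[str] = None
    gff: Optional[str] = None
    af_fixed: float = Field(0.9, gt=0.0, le=1.0)
    af_exclude: float = Field(0.1, ge=0.0, le=1.0)
    window_size: int = Field(100_000, ge=1)
    min_window_bases: int = Field(1000, ge=1)
    context_window: int = Field(75, ge=1)
    tracks: list[TrackConfig] = []
    features: list[FeatureConfig] = []
    model: ModelConfig = ModelConfig()
    cv_folds: int = Field(5, ge=2)
    subsets: dict[str, SubsetConfig] = {}
    region: Optional[str] = None
    chunk_size: int = Field(200_000, ge=1)
    seed: int = 0
    synthetic_tracks: Optional[SynthConfig] = None

    @model_validator(mode="after")
    def _check_ancestor_source(self) -> "PipelineConfig":
        if (self.ancestor_label is None) == (self.outgroup_labels is None):
            raise ValueError(
                "exactly one of ancestor_label / outgroup_labels must be set"
            )
        if self.consensus_strategy not in ("strict_consensus", "majority"):
            raise ValueError(f"unknown consensus_strategy {self.consensus_strategy!r}")
        return self

    def parsed_region(self) -> tuple[str, int, int] | None:
        if self.region is None:
            return None
        try:
            chrom, span = self.region.rsplit(":", 1)
            start, end = span.split("-")
            return chrom, int(start), int(end)
        except ValueError as exc:
            raise ConfigError(
                f"region must look like 'chrom:start-end', got {self.region!r}"
            ) from exc


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse and validate a pipeline YAML; relative paths are anchored at
    the config file's directory and required inputs must exist."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"{path}: {problems}") from exc

    base = path.parent
    cfg = _resolve_paths(cfg, base)
    for required in ("reference", "maf"):
        p = getattr(cfg, required)
        if not Path(p).exists():
            raise ConfigError(f"{path}: {required} file not found: {p}")
    for optional in ("population_vcf", "gff"):
        p = getattr(cfg, optional)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{path}: {optional} file not found: {p}")
    for t in cfg.tracks:
        if not Path(t.path).exists():
            raise ConfigError(f"{path}: track {t.name!r} file not found: {t.path}")
    return cfg


def _resolve_paths(cfg: PipelineConfig, base: Path) -> PipelineConfig:
    def resolve(p: str | None) -> str | None:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    cfg.reference = resolve(cfg.reference)
    cfg.maf = resolve(cfg.maf)
    cfg.population_vcf = resolve(cfg.population_vcf)
    cfg.gff = resolve(cfg.gff)
    cfg.out_dir = resolve(cfg.out_dir)
    for t in cfg.tracks:
        t.path = resolve(t.path)
    return cfg
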