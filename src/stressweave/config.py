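"""Pipeline configuration: one YAML/dict with paths, thresholds and seed."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

_INPUT_KEYS = (
    "edges", "degs", "gmt", "perturbations", "vcf", "consequences",
    "expression", "phenotypes", "physiology",
)


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`stressweave.pipeline.run_pipeline`.

    When all input paths are absent the pipeline generates its inputs with
    the synthetic module (parameters overridable under ``synthetic``).
    Unknown keys are rejected so typos never silently fall back to
    defaults.
    """

    outdir: str = "stressweave_out"
    seed: int = 7
    inputs: dict[str, str] = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    ppi_confidence: float = 0.7
    score_mode: str = "product"
    deg_fdr_max: float = 0.01
    deg_abs_log2fc_min: float = 0.5
    deg_pvalue_max: float | None = None
    cluster_min_size: int = 20
    enrichment_fdr: float = 0.01
    inflation_grid: tuple[float, ...] = tuple(np.round(np.arange(1.2, 5.01, 0.2), 1))
    hub_top_k: int = 3
    hub_min_metrics: int = 3
    association_ess: float = 1.0
    association_threshold: float = 0.0
    fermentation_genes: tuple[str, ...] = ()
    ros_genes: tuple[str, ...] = ()
    phenotype_directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.ppi_confidence <= 1:
            raise ConfigError("ppi_confidence must lie in (0, 1]")
        if self.score_mode not in ("product", "mean"):
            raise ConfigError("score_mode must be 'product' or 'mean'")
        if self.deg_fdr_max <= 0 or not 0 < self.enrichment_fdr <= 1:
            raise ConfigError("FDR thresholds must be positive (and <= 1)")
        if self.cluster_min_size < 0:
            raise ConfigError("cluster_min_size must be non-negative")
        if not self.inflation_grid or any(r <= 1 for r in self.inflation_grid):
            raise ConfigError("inflation_grid entries must exceed 1")
        if self.hub_top_k < 1 or not 1 <= self.hub_min_metrics <= 4:
            raise ConfigError("hub rule requires top_k >= 1, 1 <= min_metrics <= 4")
        if self.association_ess <= 0:
            raise ConfigError("association_ess must be positive")
        unknown = set(self.inputs) - set(_INPUT_KEYS)
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        for d in self.phenotype_directions.values():
            if d not in ("up", "down"):
                raise ConfigError("phenotype directions must be 'up' or 'down'")

    @property
    def use_synthetic(self) -> bool:
        return not self.inputs

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("inflation_grid", "fermentation_genes", "ros_genes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(data)
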