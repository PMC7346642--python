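"""Schema-versioned run configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    genomewide_alpha_snp: float = 5.0e-8
    genomewide_alpha_cpg: float = 3.6e-8
    n_phenotypes: int = 70
    pip_threshold: float = 0.95
    ld_concordance_r2: float = 0.75
    mr_prune_r2: float = 0.1
    cis_window_bp: int = 10_000_000
    coloc_flank_bp: int = 200_000


class ChainSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_iterations: int = 10_000
    burn_in: int = 5_000
    thinning: int = 5
    seed: int = 0


class PriorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    snp_variances: list[float] = [0.01, 0.1]
    cpg_variances: list[float] = [0.001, 0.01, 0.1]
    combined_variances: list[float] = [0.01, 0.1, 0.2]
    dirichlet_concentration: float = 1.0
    rank_int_offset: str = "half"  # or "blom"
    coloc_p1: float = 1.0e-4
    coloc_p2: float = 1.0e-4
    coloc_p12: float = 1.0e-5
    coloc_prior_sd: float = 0.15


class RunConfig(BaseModel):
    """Top-level configuration; every random stage carries an explicit seed."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    seed: int = 0
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    chain: ChainSettings = Field(default_factory=ChainSettings)
    priors: PriorConfig = Field(default_factory=PriorConfig)
    paths: dict[str, str] = Field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
    return path
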