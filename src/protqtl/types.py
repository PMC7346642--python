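"""Shared containers for genotype, methylation, protein and summary data.

Conventions used throughout the package:

* Individuals index the **rows** of genotype/methylation matrices; markers
  index the columns.  Protein panels are stored protein x individual, the
  layout in which multiplex panels are usually shipped.
* Genomic coordinates are 1-based inclusive.  BED export (0-based,
  half-open) is handled explicitly in :mod:`protqtl.io`.
* Column standardisation always uses the population convention
  (``ddof=0``), so a standardised column has mean 0 and variance exactly 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Sample identifiers of two inputs do not line up."""


class CollinearityError(ValueError):
    """A covariate design matrix is rank deficient."""


#: Canonical column order for per-marker association records.
SUMSTATS_COLUMNS = [
    "id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
]


def validate_sumstats(stats: pd.DataFrame, z_consistency: bool = True) -> pd.DataFrame:
    """Check a summary-statistics frame against the package schema.

    Verifies column presence, positive standard errors, p in (0, 1] and
    (optionally) that p is consistent with the two-sided normal
    approximation of beta/se within 10% relative error on the log scale
    wherever that approximation is informative.
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if len(stats) == 0:
        return stats
    if (stats["se"] <= 0).any():
        raise ValueError("summary statistics contain non-positive standard errors")
    if ((stats["p"] <= 0) | (stats["p"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if z_consistency:
        from scipy import stats as sps

        z = np.abs(stats["beta"].to_numpy() / stats["se"].to_numpy())
        # the normal approximation to a t-based p is poor for tiny |z| or
        # tiny n; only police clearly informative, non-underflowed records
        ok = (z > 1.0) & (z < 30.0) & (stats["n"].to_numpy() > 30)
        if ok.any():
            approx = 2.0 * sps.norm.sf(z[ok])
            rel = np.abs(np.log(stats["p"].to_numpy()[ok]) - np.log(approx)) / np.abs(
                np.log(approx)
            )
            if (rel > 0.10).any():
                bad = stats.loc[ok, "id"].to_numpy()[rel > 0.10][:5]
                raise ValueError(
                    f"p inconsistent with beta/se under normal approximation for {list(bad)}"
                )
    return stats


def empty_sumstats() -> pd.DataFrame:
    return pd.DataFrame(columns=SUMSTATS_COLUMNS)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with a per-SNP map.

    ``dosages`` holds values in [0, 2]; ``snp_map`` is indexed by SNP id
    with columns ``chrom``, ``pos``, ``effect_allele``, ``other_allele``
    and ``maf``.
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snp_map.index):
            raise ValueError("dosage columns and snp_map index disagree")
        vals = self.dosages.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index


@dataclass
class MethylationMatrix:
    """Continuous M-value-like methylation (individuals x CpGs) with probe map."""

    values: pd.DataFrame
    cpg_map: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.cpg_map.index):
            raise ValueError("methylation columns and cpg_map index disagree")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("methylation values must be finite")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class ProteinPanel:
    """Multiplex protein abundance panel (protein x individual).

    ``lod_flags`` marks measurements that fell below the assay's lowest
    limit of detection.  ``protein_map`` is indexed by protein name with the
    chromosome and transcription start site of the encoding gene, used for
    cis/trans classification downstream.
    """

    values: pd.DataFrame
    lod_flags: pd.DataFrame
    protein_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.lod_flags.shape:
            raise ValueError("values and lod_flags must share a shape")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index


@dataclass
class PreparedPhenotype:
    """Standardised residuals of one protein, ready for association scans."""

    residuals: pd.Series
    covariates_used: list[str]
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.residuals.size)


@dataclass
class TrueArchitecture:
    """Ground truth recorded by the cohort generator.

    Effects are on the standardised-phenotype scale per standardised
    marker; variance fractions are realised (empirical) shares of the
    simulated phenotype's variance.
    """

    causal_snp_ids: list[str]
    causal_cpg_ids: list[str]
    snp_effects: dict[str, float]
    cpg_effects: dict[str, float]
    true_h2_genetic: float
    true_h2_methylation: float
    confounder_effects: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for frac in (self.true_h2_genetic, self.true_h2_methylation):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("variance fractions must lie in [0, 1]")
        if self.true_h2_genetic + self.true_h2_methylation > 1.0 + 1e-12:
            raise ValueError("genetic + methylation variance fractions exceed 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrueArchitecture":
        return cls(**json.loads(text))


def check_aligned(*indexed: pd.DataFrame | pd.Series) -> pd.Index:
    """Assert that all inputs share an identical sample index; return it."""
    idx = indexed[0].index
    for other in indexed[1:]:
        if not idx.equals(other.index):
            raise AlignmentError("sample ids are not aligned across inputs")
    return idx


def standardize_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Column-standardise to mean 0, variance 1 (ddof=0); drops nothing.

    Raises on zero-variance columns, which must be filtered upstream.
    """
    vals = frame.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        bad = list(frame.columns[sd == 0][:5])
        raise ValueError(f"zero-variance columns cannot be standardised: {bad}")
    return pd.DataFrame((vals - mu) / sd, index=frame.index, columns=frame.columns)
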