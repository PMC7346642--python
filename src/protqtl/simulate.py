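"""Synthetic cohorts with known genetic/epigenetic architecture.

The generators in this module produce desk-scale analogues of the data a
plasma-proteomics cohort study works with: biallelic genotype dosages with
block linkage disequilibrium, array-style methylation values structured by
blood cell composition, batch and smoking, protein levels built from
mixture-distributed genetic and epigenetic effects, and paired regional
summary-statistic sets for colocalisation scenarios.  Every generator
records its ground truth so that recovery by the estimation modules can be
tested against known values.

LD model
--------
Within a block all SNPs share one allele frequency and each haplotype
allele copies the previous SNP's allele with probability ``ld_decay``
(first-order Markov copying), otherwise it is redrawn from the block
frequency.  Copying under a shared frequency preserves the marginal MAF
exactly while giving adjacent-SNP haplotype correlation ``ld_decay``;
blocks are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .types import (
    AlignmentError,
    GenotypeMatrix,
    MethylationMatrix,
    TrueArchitecture,
    check_aligned,
    standardize_columns,
)

_BP_SPACING = 5_000  # physical spacing between simulated SNPs / probes


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 50,
    ld_decay: float = 0.8,
    seed: int = 0,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Simulate an ``n`` x ``m`` dosage matrix with block LD.

    Parameters
    ----------
    maf_range
        Interval within (0, 0.5] from which each block's minor allele
        frequency is drawn uniformly.
    ld_block_size
        Number of adjacent SNPs forming one LD block.
    ld_decay
        Haplotype copying probability in [0, 1]; 1 gives perfect proxies
        within a block, 0 gives independent SNPs.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
    if not 0.0 <= ld_decay <= 1.0:
        raise ValueError("ld_decay must lie in [0, 1]")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be positive")

    rng = np.random.default_rng(seed)
    n_hap = 2 * n
    dosages = np.empty((n, m), dtype=np.int8)
    mafs = np.empty(m)
    start = 0
    while start < m:
        width = min(ld_block_size, m - start)
        p = rng.uniform(lo, hi)
        hap = np.empty((n_hap, width), dtype=np.int8)
        hap[:, 0] = rng.random(n_hap) < p
        for j in range(1, width):
            copy = rng.random(n_hap) < ld_decay
            fresh = rng.random(n_hap) < p
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        dosages[:, start : start + width] = hap[0::2] + hap[1::2]
        mafs[start : start + width] = p
        start += width

    snp_ids = [f"rs{j + 1}" for j in range(m)]
    sample_ids = [f"id_{i + 1}" for i in range(n)]
    snp_map = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * _BP_SPACING,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": mafs,
        },
        index=pd.Index(snp_ids, name="id"),
    )
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=sample_ids, columns=snp_ids),
        snp_map=snp_map,
    )


class MethylationSim(NamedTuple):
    """Methylation generator output: data, covariates and designated probes."""

    methylation: MethylationMatrix
    covariates: pd.DataFrame
    smoking_probes: list[str]


def simulate_methylation(
    n: int,
    m: int,
    n_cell_types: int = 5,
    batch_levels: int = 3,
    smoking_prevalence: float = 0.3,
    seed: int = 0,
    n_smoking_probes: int | None = None,
    smoking_effect: float = -2.0,
    cell_loading_sd: float = 1.0,
    batch_sd: float = 0.3,
) -> MethylationSim:
    """Simulate M-value-like methylation with cell, batch and smoking structure.

    Each probe is ``intercept + cell-proportion loading + batch shift +
    smoking effect (designated probes only) + N(0,1) noise``.  The covariate
    table carries per-individual cell proportions (columns ``cell_1..K``,
    rows summing to 1 — drop one column before building a design matrix),
    a categorical ``batch`` label and a 0/1 ``smoking`` indicator.
    """
    if n < 1 or m < 1:
        raise ValueError("need n, m >= 1")
    if not 0.0 <= smoking_prevalence <= 1.0:
        raise ValueError("smoking_prevalence must lie in [0, 1]")
    if n_cell_types < 1 or batch_levels < 1:
        raise ValueError("need at least one cell type and one batch level")

    rng = np.random.default_rng(seed)
    sample_ids = [f"id_{i + 1}" for i in range(n)]
    probe_ids = [f"cg{j + 1:07d}" for j in range(m)]

    # blood-like composition: a dominant type plus progressively rarer ones
    alpha = np.array([10.0 / (k + 1) for k in range(n_cell_types)])
    props = rng.dirichlet(alpha, size=n)
    batch = rng.integers(0, batch_levels, size=n)
    smoking = (rng.random(n) < smoking_prevalence).astype(int)

    intercept = rng.normal(0.0, 2.0, size=m)
    loadings = rng.normal(0.0, cell_loading_sd, size=(n_cell_types, m))
    batch_shift = rng.normal(0.0, batch_sd, size=(batch_levels, m))

    if n_smoking_probes is None:
        n_smoking_probes = max(1, m // 100)
    n_smoking_probes = min(n_smoking_probes, m)
    smoke_idx = rng.choice(m, size=n_smoking_probes, replace=False)

    values = intercept[None, :] + props @ loadings + batch_shift[batch, :]
    values[:, smoke_idx] += smoking[:, None] * smoking_effect
    values += rng.normal(0.0, 1.0, size=(n, m))

    cpg_map = pd.DataFrame(
        {
            "chrom": "2",
            "pos": np.arange(1, m + 1) * _BP_SPACING,
            "probe_id": probe_ids,
        },
        index=pd.Index(probe_ids, name="id"),
    )
    covariates = pd.DataFrame(
        {f"cell_{k + 1}": props[:, k] for k in range(n_cell_types)},
        index=sample_ids,
    )
    covariates["batch"] = pd.Categorical([f"b{b + 1}" for b in batch])
    covariates["smoking"] = smoking
    meth = MethylationMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=probe_ids),
        cpg_map=cpg_map,
    )
    return MethylationSim(meth, covariates, [probe_ids[j] for j in sorted(smoke_idx)])


@dataclass
class ArchitectureConfig:
    """Target architecture for one simulated protein.

    ``snp_component_variances``/``cpg_component_variances`` define the
    Gaussian mixture classes from which raw causal effects are drawn, with
    ``*_component_probs`` their class proportions; effects are then rescaled
    jointly so the realised variance share matches the ``h2_*`` target.
    ``confounder_effects`` maps covariate column names to effects on the
    standardised-covariate scale (e.g. smoking acting on the protein itself,
    which is what creates the attenuation pattern in adjusted scans).
    """

    h2_genetic: float = 0.2
    h2_methylation: float = 0.2
    n_causal_snps: int = 10
    n_causal_cpgs: int = 10
    snp_component_variances: tuple[float, ...] = (0.01, 0.1)
    snp_component_probs: tuple[float, ...] = (0.8, 0.2)
    cpg_component_variances: tuple[float, ...] = (0.001, 0.01, 0.1)
    cpg_component_probs: tuple[float, ...] = (0.7, 0.2, 0.1)
    confounder_effects: dict[str, float] = field(default_factory=dict)
    name: str = "protein_1"

    def __post_init__(self) -> None:
        if self.h2_genetic < 0 or self.h2_methylation < 0:
            raise ValueError("variance targets must be non-negative")
        if self.h2_genetic + self.h2_methylation > 1.0:
            raise ValueError("target variance shares must sum to at most 1")


def _mixture_effects(
    rng: np.random.Generator,
    n_causal: int,
    variances: Sequence[float],
    probs: Sequence[float],
) -> np.ndarray:
    comp = rng.choice(len(variances), size=n_causal, p=np.asarray(probs) / np.sum(probs))
    return rng.normal(0.0, 1.0, size=n_causal) * np.sqrt(np.asarray(variances)[comp])


def _scaled_component(raw: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Rescale a centred component vector to realised variance ``target_var``."""
    raw = raw - raw.mean()
    sd = raw.std()
    if sd == 0:
        return raw, 0.0
    scale = np.sqrt(target_var) / sd
    return raw * scale, scale


def simulate_proteins(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    covariates: pd.DataFrame,
    arch_config: ArchitectureConfig,
    seed: int = 0,
) -> tuple[pd.Series, TrueArchitecture]:
    """Build one protein from mixture-distributed genetic/epigenetic effects.

    The phenotype is assembled as ``y = g + m + c + e`` where ``g``/``m``
    are causal-marker contributions rescaled on their realised variances to
    hit the ``h2`` targets exactly, ``c`` collects confounder effects and
    the noise ``e`` is empirically orthogonalised against the other parts
    and scaled so that ``var(y) = 1`` exactly.  Realised variance shares
    therefore equal the recorded ground truth by construction.
    """
    idx = check_aligned(genotypes.dosages, methylation.values, covariates)
    n = len(idx)
    rng = np.random.default_rng(seed)
    cfg = arch_config

    def causal_part(frame: pd.DataFrame, n_causal, variances, probs, h2):
        if h2 == 0.0 or n_causal == 0:
            return np.zeros(n), [], np.zeros(0)
        cols = frame.columns.to_numpy()
        polymorphic = frame.to_numpy().std(axis=0) > 0
        pool = cols[polymorphic]
        if len(pool) < n_causal:
            raise ValueError("not enough polymorphic markers for requested causal set")
        chosen = list(rng.choice(pool, size=n_causal, replace=False))
        raw_beta = _mixture_effects(rng, n_causal, variances, probs)
        X = standardize_columns(frame[chosen])
        g = X.to_numpy() @ raw_beta
        g, scale = _scaled_component(g, h2)
        return g, chosen, raw_beta * scale

    g, causal_snps, snp_beta = causal_part(
        genotypes.dosages,
        cfg.n_causal_snps,
        cfg.snp_component_variances,
        cfg.snp_component_probs,
        cfg.h2_genetic,
    )
    mth, causal_cpgs, cpg_beta = causal_part(
        methylation.values,
        cfg.n_causal_cpgs,
        cfg.cpg_component_variances,
        cfg.cpg_component_probs,
        cfg.h2_methylation,
    )

    c = np.zeros(n)
    for name, eff in cfg.confounder_effects.items():
        if name not in covariates.columns:
            raise KeyError(f"confounder {name!r} not in covariate table")
        col = covariates[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            raise ValueError(f"confounder {name!r} has zero variance")
        c += eff * (col - col.mean()) / sd

    signal = g + mth + c
    var_signal = signal.var()
    if var_signal >= 1.0:
        raise ValueError(
            "targets plus confounder effects leave no room for noise "
            f"(var(signal)={var_signal:.3f} >= 1)"
        )
    e = rng.normal(0.0, 1.0, size=n)
    basis = np.column_stack([np.ones(n), g, mth, c])
    e -= basis @ np.linalg.lstsq(basis, e, rcond=None)[0]
    e *= np.sqrt(1.0 - var_signal) / e.std()

    y = pd.Series(signal + e, index=idx, name=cfg.name)
    arch = TrueArchitecture(
        causal_snp_ids=causal_snps,
        causal_cpg_ids=causal_cpgs,
        snp_effects={s: float(b) for s, b in zip(causal_snps, snp_beta)},
        cpg_effects={s: float(b) for s, b in zip(causal_cpgs, cpg_beta)},
        true_h2_genetic=float(g.var()),
        true_h2_methylation=float(mth.var()),
        confounder_effects=dict(cfg.confounder_effects),
        seed=seed,
    )
    return y, arch


_SCENARIOS = ("shared_causal", "distinct_causal", "one_trait_only", "no_signal")


def simulate_summary_pair(
    scenario: str,
    n_snps: int = 500,
    n1: int = 10_000,
    n2: int = 10_000,
    seed: int = 0,
    target_z: float = 12.0,
    ld_decay: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate two regional summary-statistic sets over a shared LD structure.

    Individual-level data for the two traits are simulated from one
    genotype pool (so betas, ses and p-values are internally consistent by
    construction) and summarised with the marginal scan.  ``target_z`` sets
    the expected association z-score at the causal variant.

    Returns ``(stats1, stats2, r2_matrix)``.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")
    if n_snps < 10:
        raise ValueError("need at least 10 SNPs in the region")

    from .scan import ols_scan  # deferred: avoids an import cycle

    rng = np.random.default_rng(seed)
    pool = simulate_genotypes(
        n1 + n2,
        n_snps,
        maf_range=(0.1, 0.5),
        ld_block_size=n_snps,
        ld_decay=ld_decay,
        seed=int(rng.integers(2**31 - 1)),
    )
    dos = pool.dosages.to_numpy(dtype=float)
    r2 = pd.DataFrame(
        np.corrcoef(dos, rowvar=False) ** 2,
        index=pool.dosages.columns,
        columns=pool.dosages.columns,
    )

    mid = n_snps // 2
    if scenario == "distinct_causal":
        # find a partner for the mid SNP in low LD
        low = np.flatnonzero(r2.to_numpy()[mid] < 0.05)
        if low.size == 0:
            raise ValueError("no SNP pair in sufficiently low LD; lower ld_decay")
        partner = int(low[np.argmax(np.abs(low - mid))])
        causal = {"trait1": mid, "trait2": partner}
    elif scenario == "shared_causal":
        causal = {"trait1": mid, "trait2": mid}
    elif scenario == "one_trait_only":
        causal = {"trait1": mid, "trait2": None}
    else:
        causal = {"trait1": None, "trait2": None}

    halves = {"trait1": slice(0, n1), "trait2": slice(n1, n1 + n2)}
    out = []
    for trait, nn in (("trait1", n1), ("trait2", n2)):
        sub = pool.dosages.iloc[halves[trait]]
        j = causal[trait]
        y = rng.normal(0.0, 1.0, size=nn)
        if j is not None:
            x = sub.iloc[:, j].to_numpy(dtype=float)
            x = (x - x.mean()) / x.std()
            r = target_z / np.sqrt(nn + target_z**2)
            y = r * x + np.sqrt(1.0 - r**2) * y
        geno = GenotypeMatrix(dosages=sub, snp_map=pool.snp_map)
        pheno = pd.Series((y - y.mean()) / y.std(), index=sub.index)
        out.append(ols_scan(geno, pheno))
    return out[0], out[1], r2
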