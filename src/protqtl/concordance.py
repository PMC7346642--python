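"""Cross-method triangulation: LD, cis/trans classification, effect comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix


@dataclass
class HitSet:
    """Significant markers for one protein from one method.

    ``criterion`` is "p" for OLS/mixed hits and "pip" for Bayesian hits;
    ``markers`` needs columns id, chrom, pos, beta and the criterion value.
    """

    method: str  # "ols" | "mixed" | "bayes"
    protein: str
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        expected = "pip" if self.method == "bayes" else "p"
        if expected not in self.markers.columns:
            raise ValueError(f"{self.method} hitset must carry a {expected!r} column")


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Invariant to allele flips (2 - g) of either argument.  Monomorphic
    input is an error: its LD with anything is undefined.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("dosage vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic dosage vector has undefined LD")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def classify_cis_trans(
    snp_pos: tuple[str, int],
    gene_tss: tuple[str, int],
    window_bp: int = 10_000_000,
) -> str:
    """Classify a variant as cis (within the TSS window) or trans.

    A variant at exactly the window boundary is cis (inclusive "within").
    Different chromosomes are always trans.
    """
    snp_chrom, pos = snp_pos
    gene_chrom, tss = gene_tss
    if str(snp_chrom) != str(gene_chrom):
        return "trans"
    return "cis" if abs(int(pos) - int(tss)) <= window_bp else "trans"


def cis_fraction(classifications) -> float:
    """Percentage of classifications that are cis."""
    labels = list(classifications)
    if not labels:
        raise ValueError("no classifications supplied")
    return 100.0 * sum(1 for c in labels if c == "cis") / len(labels)


def triangulate(
    hitsets: list[HitSet],
    genotypes: GenotypeMatrix,
    ld_threshold: float = 0.75,
) -> pd.DataFrame:
    """Markers concordant across all hitsets, directly or via high-LD proxies.

    A marker is concordant iff every hitset contains it, or contains some
    marker in LD r2 strictly above ``ld_threshold`` with it (computed on
    the analysis sample's dosages).  Returns one row per (marker, method)
    with the linking variant and its r2.  Symmetric in hitset order.
    """
    if len(hitsets) < 2:
        raise ValueError("need at least two hitsets to triangulate")
    dosages = genotypes.dosages

    def _require(marker_id: str) -> np.ndarray:
        if marker_id not in dosages.columns:
            raise KeyError(f"marker {marker_id!r} absent from genotype matrix")
        return dosages[marker_id].to_numpy(dtype=float)

    candidates = sorted({str(i) for hs in hitsets for i in hs.markers["id"]})
    rows = []
    for cand in candidates:
        g_c = _require(cand)
        links = []
        for hs in hitsets:
            ids = [str(i) for i in hs.markers["id"]]
            if cand in ids:
                links.append((hs.method, cand, 1.0))
                continue
            best = None
            for other in ids:
                r2 = ld_r2(g_c, _require(other))
                if r2 > ld_threshold and (best is None or r2 > best[1]):
                    best = (other, r2)
            if best is None:
                links = None
                break
            links.append((hs.method, best[0], best[1]))
        if links is None:
            continue
        for method, link, r2 in links:
            rows.append(
                {
                    "protein": hitsets[0].protein,
                    "marker": cand,
                    "method": method,
                    "linking_variant": link,
                    "r2": r2,
                }
            )
    return pd.DataFrame(rows, columns=["protein", "marker", "method", "linking_variant", "r2"])


def effect_correlation(
    betas_a,
    betas_b,
    effect_alleles_a=None,
    effect_alleles_b=None,
    align_alleles: bool = False,
) -> dict:
    """Pearson correlation of matched effect sizes with a Fisher-z 95% CI.

    With ``align_alleles`` the sign of ``betas_b`` is flipped wherever the
    stated effect alleles differ between the two sets.
    """
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float).copy()
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 matched effect pairs")
    if align_alleles:
        if effect_alleles_a is None or effect_alleles_b is None:
            raise ValueError("allele alignment requested but alleles not supplied")
        flip = np.asarray(effect_alleles_a) != np.asarray(effect_alleles_b)
        b[flip] = -b[flip]
    r = float(np.corrcoef(a, b)[0, 1])
    n = a.size
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n - 3)
    return {
        "r": r,
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "n": n,
    }


def maf_effect_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Report of minor allele frequency versus absolute effect size.

    A descriptive utility over summary statistics (no test): returns maf,
    |beta| per marker, sorted by maf, for plotting the inverse
    frequency/effect-size relationship.
    """
    eaf = stats["eaf"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    out = pd.DataFrame(
        {"id": stats["id"], "maf": maf, "abs_beta": stats["beta"].abs()}
    )
    return out.sort_values("maf").reset_index(drop=True)
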