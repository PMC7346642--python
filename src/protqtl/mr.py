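"""Two-sample Mendelian randomisation: Wald ratio, IVW, MR-Egger.

Instruments are summary-level (beta, se) pairs for an exposure (protein
level) and an outcome (disease or trait).  Harmonisation aligns effect
alleles between the two sets before estimation, dropping strand-ambiguous
palindromic variants; LD pruning keeps the sentinel variant of each
correlated clump.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .concordance import ld_r2
from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class MRResult:
    method: str  # "wald" | "ivw" | "egger"
    beta: float
    se: float
    p: float
    n_variants: int
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if self.method == "wald" and self.n_variants != 1:
            raise ValueError("wald ratio uses exactly one variant")


def harmonise(exposure: pd.DataFrame, outcome: pd.DataFrame, drop_ambiguous: bool = True) -> pd.DataFrame:
    """Inner-join exposure/outcome stats on id with allele alignment.

    Outcome betas are sign-flipped where its effect/other alleles are
    swapped relative to the exposure; variants whose alleles cannot be
    reconciled, and (by default) strand-ambiguous A/T and C/G variants,
    are dropped with a log entry.  Applying harmonisation twice is the
    identity.
    """
    j = exposure.merge(outcome, on="id", suffixes=("_exp", "_out"))
    keep, flip = [], []
    for _, row in j.iterrows():
        ea_e, oa_e = str(row["effect_allele_exp"]), str(row["other_allele_exp"])
        ea_o, oa_o = str(row["effect_allele_out"]), str(row["other_allele_out"])
        if drop_ambiguous and frozenset((ea_e, oa_e)) in _AMBIGUOUS:
            logger.info("harmonise: dropping strand-ambiguous variant %s", row["id"])
            keep.append(False)
            flip.append(False)
            continue
        if (ea_e, oa_e) == (ea_o, oa_o):
            keep.append(True)
            flip.append(False)
        elif (ea_e, oa_e) == (oa_o, ea_o):
            keep.append(True)
            flip.append(True)
        else:
            logger.info("harmonise: dropping allele-mismatched variant %s", row["id"])
            keep.append(False)
            flip.append(False)
    j = j[np.asarray(keep)].reset_index(drop=True)
    flip = np.asarray(flip)[np.asarray(keep)]
    j.loc[flip, "beta_out"] = -j.loc[flip, "beta_out"]
    j.loc[flip, ["effect_allele_out", "other_allele_out"]] = j.loc[
        flip, ["other_allele_out", "effect_allele_out"]
    ].to_numpy()
    if "eaf_out" in j.columns:
        j.loc[flip, "eaf_out"] = 1.0 - j.loc[flip, "eaf_out"]
    return j


def ld_prune(
    stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """Greedy LD pruning ordered by ascending p-value.

    The most significant (sentinel) variant always survives; each further
    variant is kept iff its r2 with every kept variant is strictly below
    ``r2_max``, computed on the analysis sample's dosages.
    """
    order = stats.sort_values("p", kind="mergesort")
    kept: list[str] = []
    for marker in order["id"].astype(str):
        if marker not in genotypes.dosages.columns:
            raise KeyError(f"marker {marker!r} absent from genotype matrix")
        g = genotypes.dosages[marker].to_numpy(dtype=float)
        if all(ld_r2(g, genotypes.dosages[k].to_numpy(dtype=float)) < r2_max for k in kept):
            kept.append(marker)
    return stats[stats["id"].astype(str).isin(kept)].reset_index(drop=True)


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
) -> MRResult:
    """Single-instrument causal estimate: ratio of outcome to exposure effect.

    The first-order delta-method standard error ``se_out/|beta_exp|``
    ignores exposure uncertainty, which is accurate for strong instruments
    (|beta_exp/se_exp| large).
    """
    if beta_exposure == 0:
        raise ValueError("zero exposure beta: instrument undefined")
    beta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    p = float(np.clip(2.0 * sps.norm.sf(abs(beta / se)), 1e-320, 1.0))
    return MRResult(method="wald", beta=float(beta), se=float(se), p=p, n_variants=1)


def ivw(harmonised: pd.DataFrame) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate over >= 2 instruments.

    Weighted least squares of outcome betas on exposure betas through the
    origin with weights 1/se_out^2; the fixed-effect standard error is
    1/sqrt(sum w * beta_exp^2).
    """
    if len(harmonised) < 2:
        raise ValueError("need >= 2 harmonised variants; use wald_ratio for one")
    bx = harmonised["beta_exp"].to_numpy(dtype=float)
    by = harmonised["beta_out"].to_numpy(dtype=float)
    w = 1.0 / harmonised["se_out"].to_numpy(dtype=float) ** 2
    denom = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    p = float(np.clip(2.0 * sps.norm.sf(abs(beta / se)), 1e-320, 1.0))
    return MRResult(method="ivw", beta=beta, se=se, p=p, n_variants=len(harmonised))


def egger(harmonised: pd.DataFrame) -> MRResult:
    """MR-Egger regression: weighted fit with intercept over >= 3 instruments.

    Exposure betas are oriented non-negative (flipping the outcome beta
    with them); the intercept estimates directional pleiotropy, and its
    p-value is the pleiotropy test.
    """
    if len(harmonised) < 3:
        raise ValueError("need >= 3 harmonised variants for MR-Egger")
    bx = harmonised["beta_exp"].to_numpy(dtype=float).copy()
    by = harmonised["beta_out"].to_numpy(dtype=float).copy()
    flip = bx < 0
    bx[flip] = -bx[flip]
    by[flip] = -by[flip]
    w = 1.0 / harmonised["se_out"].to_numpy(dtype=float) ** 2
    model = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    return MRResult(
        method="egger",
        beta=float(model.params[1]),
        se=float(model.bse[1]),
        p=float(np.clip(model.pvalues[1], 1e-320, 1.0)),
        n_variants=len(harmonised),
        egger_intercept=float(model.params[0]),
        egger_intercept_p=float(model.pvalues[0]),
    )
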