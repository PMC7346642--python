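"""Bayesian colocalisation over regional summary statistics.

Single-SNP evidence is summarised by the Wakefield approximate Bayes
factor; per-hypothesis weights are assembled from the per-SNP ABFs of two
traits under the standard five hypotheses (no causal variant, causal for
trait 1 only, trait 2 only, two distinct causal variants, one shared
causal variant).  All accumulation is in log space, so posteriors stay
finite for |z| well beyond 50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: coloc-style default priors: per-SNP causal for trait 1 / trait 2 / both.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
#: Default effect-size prior sd for a quantitative trait.
DEFAULT_PRIOR_SD = 0.15


@dataclass
class ColocResult:
    pp: dict[str, float]  # keys pp0..pp4
    n_snps: int
    priors: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array([self.pp[k] for k in ("pp0", "pp1", "pp2", "pp3", "pp4")])
        if abs(vals.sum() - 1.0) > 1e-10 or (vals < -1e-12).any():
            raise ValueError("posterior probabilities must be in [0,1] and sum to 1")

    @property
    def modal_hypothesis(self) -> str:
        return max(self.pp, key=self.pp.get)


def extract_region(
    stats: pd.DataFrame,
    center: tuple[str, int],
    flank_bp: int = 200_000,
) -> pd.DataFrame:
    """Subset summary statistics to ±``flank_bp`` around a position (inclusive)."""
    chrom, pos = center
    sel = (stats["chrom"].astype(str) == str(chrom)) & (
        (stats["pos"] - int(pos)).abs() <= flank_bp
    )
    region = stats[sel].reset_index(drop=True)
    if len(region) == 0:
        raise ValueError(f"no SNPs within {flank_bp} bp of {chrom}:{pos}")
    return region


def wakefield_log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for a single association.

    With z = beta/se, V = se^2 and W = prior_sd^2, r = W/(V+W):
    log ABF = 0.5*(log(1-r) + r*z^2).  Positive values favour a real
    effect; at z = 0 the Occam factor 0.5*log(1-r) penalises the alternative.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.isfinite(beta).all() and np.isfinite(se).all()):
        raise ValueError("beta/se must be finite")
    if (se <= 0).any() or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    z = beta / se
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def coloc_posteriors(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd: tuple[float, float] = (DEFAULT_PRIOR_SD, DEFAULT_PRIOR_SD),
) -> ColocResult:
    """Posterior probabilities of the five colocalisation hypotheses.

    The two frames are inner-joined on marker id (dropped SNPs logged).
    Per-hypothesis log weights:
        H0: 0
        H1: log p1  + logsum(l1)
        H2: log p2  + logsum(l2)
        H3: log p1 + log p2 + log(sum_i l1 * sum_j l2 - sum_i l1*l2)
        H4: log p12 + logsum(l1 + l2)
    normalised by log-sum-exp.  Swapping the traits swaps pp1 and pp2 and
    leaves pp0, pp3, pp4 unchanged.
    """
    joined = stats1.merge(stats2, on="id", suffixes=("_1", "_2"))
    dropped = (len(stats1) - len(joined), len(stats2) - len(joined))
    if dropped != (0, 0):
        logger.info("coloc: dropped %d/%d unmatched SNPs from trait1/trait2", *dropped)
    if len(joined) < 2:
        raise ValueError("need at least 2 shared SNPs for colocalisation")

    l1 = wakefield_log_abf(joined["beta_1"], joined["se_1"], prior_sd[0])
    l2 = wakefield_log_abf(joined["beta_2"], joined["se_2"], prior_sd[1])
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # log(exp(s1+s2) - exp(s12)), guarded: the cross term dominates
    both = s1 + s2
    if s12 >= both:
        l_h3_sum = -np.inf
    else:
        l_h3_sum = both + np.log1p(-np.exp(s12 - both))

    lw = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + l_h3_sum,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lw - logsumexp(lw))
    return ColocResult(
        pp={f"pp{k}": float(pp[k]) for k in range(5)},
        n_snps=len(joined),
        priors={"p1": p1, "p2": p2, "p12": p12,
                "prior_sd_1": prior_sd[0], "prior_sd_2": prior_sd[1]},
    )
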