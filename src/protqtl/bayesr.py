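"""Grouped spike-and-slab Bayesian mixture regression (Gibbs sampling).

The model regresses a standardised phenotype jointly on one or more
column-standardised marker groups (e.g. all SNPs and all CpGs), with a
per-marker prior mixing a point mass at zero and Gaussian slabs of
increasing variance:

    y = W a + sum_g X_g b_g + e
    b_gj ~ pi_g0 d0 + sum_k pi_gk N(0, c_gk * sigma2_g)
    e   ~ N(0, sigma2_e I)

Slab variances ``c_gk`` are fractions multiplying the group variance
hyperparameter ``sigma2_g`` (the BayesR convention); a per-group scaled
inverse-chi-square conditional updates ``sigma2_g`` and ``sigma2_e``, and
mixture proportions get a Dirichlet conditional.  Group variance shares
are computed per retained draw as ``var(X_g b_g)/var(y)`` on the analysis
sample, so they are sample-specific and bounded sensibly; attribution to
a slab component k within a group is ``cov(u_k, u_total)/var(y)``, which
sums exactly to the group share within every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import PreparedPhenotype
from .phenotype import build_design

#: Stand-alone GWAS slab variances (fractions of sigma2_g).
SNP_PRIOR_VARIANCES = (0.01, 0.1)
#: Stand-alone EWAS slab variances.
CPG_PRIOR_VARIANCES = (0.001, 0.01, 0.1)
#: Combined genetic + epigenetic run (both groups share this vector).
COMBINED_PRIOR_VARIANCES = (0.01, 0.1, 0.2)


@dataclass
class OmicsGroup:
    """A named marker block entering the joint model.

    ``values`` must be column-standardised (mean 0, variance 1, ddof=0);
    the fit refuses non-standardised input rather than silently rescaling.
    """

    name: str
    values: pd.DataFrame


@dataclass
class MixturePrior:
    component_variances: tuple[float, ...]
    dirichlet_concentration: tuple[float, ...] | float = 1.0

    def __post_init__(self) -> None:
        cv = np.asarray(self.component_variances, dtype=float)
        if (cv <= 0).any() or (np.diff(cv) <= 0).any():
            raise ValueError("component variances must be positive and strictly increasing")
        if np.isscalar(self.dirichlet_concentration):
            self.dirichlet_concentration = tuple(
                [float(self.dirichlet_concentration)] * (len(cv) + 1)
            )
        elif len(self.dirichlet_concentration) != len(cv) + 1:
            raise ValueError("need one concentration per component including the spike")


@dataclass
class ChainConfig:
    n_iterations: int = 10_000
    burn_in: int = 5_000
    thinning: int = 5
    seed: int = 0
    pip_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def retained_draws(self) -> int:
        return (self.n_iterations - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class PosteriorSummary:
    """Retained Gibbs draws and per-marker posterior summaries."""

    markers: pd.DataFrame  # id, group, pip, post_mean, post_sd
    share_draws: pd.DataFrame  # retained draws x groups
    comp_share_draws: dict[str, np.ndarray]  # group -> (draws, K)
    component_variances: dict[str, tuple[float, ...]]
    sigma2_group: pd.DataFrame
    sigma2_e: np.ndarray
    pi_draws: dict[str, np.ndarray]  # group -> (draws, K+1), spike first
    chain: ChainConfig
    pip_threshold: float = 0.95

    @property
    def n_draws(self) -> int:
        return len(self.share_draws)


def fit_bayes_mixture(
    groups: Sequence[OmicsGroup],
    phenotype,
    fixed_covariates: pd.DataFrame | None = None,
    priors: Mapping[str, MixturePrior] | None = None,
    chain: ChainConfig | None = None,
    include_intercept: bool = True,
    variance_scaling: str = "relative",
    update_hyperparams: bool = True,
    update_pi: bool = True,
    sigma2_g_init: float = 1.0,
    sigma2_e_init: float = 1.0,
    nu0: float = 0.001,
    s02: float = 0.001,
) -> PosteriorSummary:
    """Run the Gibbs sampler and summarise the posterior.

    Parameters of note
    ------------------
    variance_scaling
        ``"relative"`` (default): slab variances are fractions of the
        sampled group hyperparameter sigma2_g.  ``"absolute"``: they are
        fixed absolute variances (sigma2_g pinned at 1 and not updated).
    update_hyperparams / update_pi
        Disabling these freezes sigma2 (and/or mixture proportions) at
        their initial values — used for exact-oracle comparisons.
    """
    from ._gibbs import run_chain

    chain = chain or ChainConfig()
    if variance_scaling not in ("relative", "absolute"):
        raise ValueError("variance_scaling must be 'relative' or 'absolute'")
    if priors is None:
        priors = {}
    y = phenotype.residuals if isinstance(phenotype, PreparedPhenotype) else phenotype
    yv = np.asarray(y, dtype=float)
    n = yv.size

    blocks, group_names, group_of, comp_off, comp_var, dir_conc = [], [], [], [0], [], []
    marker_ids: list[str] = []
    for g, grp in enumerate(groups):
        vals = grp.values.to_numpy(dtype=float)
        if vals.shape[0] != n:
            raise ValueError(f"group {grp.name!r} has {vals.shape[0]} rows; phenotype has {n}")
        mu = vals.mean(axis=0)
        var = vals.var(axis=0)
        if (np.abs(mu) > 1e-6).any() or (np.abs(var - 1.0) > 1e-4).any():
            raise ValueError(
                f"group {grp.name!r} columns are not standardised to mean 0, variance 1"
            )
        prior = priors.get(grp.name) if grp.name in priors else MixturePrior(SNP_PRIOR_VARIANCES)
        blocks.append(vals)
        group_names.append(grp.name)
        group_of.extend([g] * vals.shape[1])
        comp_off.append(comp_off[-1] + len(prior.component_variances))
        comp_var.extend(prior.component_variances)
        dir_conc.extend(prior.dirichlet_concentration)
        marker_ids.extend(str(c) for c in grp.values.columns)

    X = np.asfortranarray(np.concatenate(blocks, axis=1))
    m = X.shape[1]
    if include_intercept or fixed_covariates is not None:
        design = build_design(fixed_covariates, y.index if hasattr(y, "index") else pd.RangeIndex(n))
        if not include_intercept:
            design = design.drop(columns=["intercept"])
        W = design.to_numpy(dtype=float)
    else:
        W = np.zeros((n, 0))
    q = W.shape[1]
    if q > 0:
        WtWinv = np.linalg.inv(W.T @ W)
        WtWinv_chol = np.linalg.cholesky(WtWinv)
    else:
        WtWinv = np.zeros((0, 0))
        WtWinv_chol = np.zeros((0, 0))

    if chain.retained_draws < 100:
        import warnings

        warnings.warn(
            f"only {chain.retained_draws} retained draws; posterior summaries will be noisy",
            stacklevel=2,
        )

    update_s2g = update_hyperparams and variance_scaling == "relative"
    update_s2e = update_hyperparams

    (
        share_draws,
        comp_share_draws,
        s2g_draws,
        s2e_draws,
        pi_draws,
        beta_sum,
        beta_sq,
        pip_cnt,
    ) = run_chain(
        X,
        yv,
        W,
        WtWinv,
        WtWinv_chol,
        np.asarray(group_of, dtype=np.int64),
        np.asarray(comp_off, dtype=np.int64),
        np.asarray(comp_var, dtype=float),
        np.asarray(dir_conc, dtype=float),
        chain.n_iterations,
        chain.burn_in,
        chain.thinning,
        chain.seed,
        update_s2g,
        update_s2e,
        update_pi,
        np.full(len(groups), float(sigma2_g_init)),
        float(sigma2_e_init),
        float(nu0),
        float(s02),
    )

    D = share_draws.shape[0]
    post_mean = beta_sum / D
    post_var = np.maximum(beta_sq / D - post_mean**2, 0.0)
    markers = pd.DataFrame(
        {
            "id": marker_ids,
            "group": [group_names[g] for g in group_of],
            "pip": pip_cnt / D,
            "post_mean": post_mean,
            "post_sd": np.sqrt(post_var),
        }
    )
    comp_by_group = {}
    pi_by_group = {}
    pi_pos = 0
    for g, name in enumerate(group_names):
        k0, k1 = comp_off[g], comp_off[g + 1]
        comp_by_group[name] = comp_share_draws[:, k0:k1]
        kg = k1 - k0
        pi_by_group[name] = pi_draws[:, pi_pos : pi_pos + kg + 1]
        pi_pos += kg + 1
    return PosteriorSummary(
        markers=markers,
        share_draws=pd.DataFrame(share_draws, columns=group_names),
        comp_share_draws=comp_by_group,
        component_variances={
            name: tuple(comp_var[comp_off[g] : comp_off[g + 1]])
            for g, name in enumerate(group_names)
        },
        sigma2_group=pd.DataFrame(s2g_draws, columns=group_names),
        sigma2_e=s2e_draws,
        pi_draws=pi_by_group,
        chain=chain,
        pip_threshold=chain.pip_threshold,
    )


def significant_markers(posterior: PosteriorSummary, pip_threshold: float = 0.95) -> pd.DataFrame:
    """Markers with posterior inclusion probability >= the threshold.

    The comparison is inclusive (a PIP of exactly 0.95 counts); the result
    is sorted by PIP descending.
    """
    hits = posterior.markers[posterior.markers["pip"] >= pip_threshold]
    return hits.sort_values("pip", ascending=False).reset_index(drop=True)


def variance_partition(posterior: PosteriorSummary) -> pd.DataFrame:
    """Per-group variance shares: posterior mean, 95% CI, component attribution.

    Credible intervals are the 2.5th/97.5th percentiles of the retained
    share draws.  Component columns report the mean attribution of each
    slab component; within every draw the attributions sum exactly to the
    group share.
    """
    if posterior.n_draws < 100:
        raise ValueError("need at least 100 retained draws for a stable partition")
    rows = []
    for name in posterior.share_draws.columns:
        draws = posterior.share_draws[name].to_numpy()
        row = {
            "group": name,
            "mean_share": float(draws.mean()),
            "ci_low": float(np.percentile(draws, 2.5)),
            "ci_high": float(np.percentile(draws, 97.5)),
        }
        comp = posterior.comp_share_draws[name]
        for k, cv in enumerate(posterior.component_variances[name]):
            row[f"component_{cv:g}"] = float(comp[:, k].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_variance_posteriors(draws_alone, draws_conditional) -> tuple[float, float]:
    """Welch two-sample t-test between two variance-share draw vectors.

    Used to ask whether the share estimated for a data type alone differs
    from its estimate conditional on the other data type.  Degenerate
    zero-variance inputs with equal means return (0, 1) by convention.
    """
    a = np.asarray(draws_alone, dtype=float)
    b = np.asarray(draws_conditional, dtype=float)
    if a.size < 30 or b.size < 30:
        raise ValueError("need at least 30 draws per vector")
    if a.var() == 0 and b.var() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
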