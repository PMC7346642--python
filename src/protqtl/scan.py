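"""Marginal association scans: OLS GWAS/EWAS, conditional analysis, MLM.

Per-marker OLS uses the Frisch–Waugh–Lovell decomposition: phenotype and
markers are projected off the covariate design once, then each marker is
fitted by simple regression on the residualised data.  The mixed-model
EWAS fits a methylation-relatedness random effect (M M'/m) by REML with a
single eigendecomposition reused across probes (EMMAX-style).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .phenotype import build_design
from .types import (
    GenotypeMatrix,
    MethylationMatrix,
    PreparedPhenotype,
    SUMSTATS_COLUMNS,
)

logger = logging.getLogger(__name__)

#: Smallest p-value reported; underflow below this is clamped.
P_FLOOR = 1e-320

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_MEDIAN_1DF = float(sps.chi2.ppf(0.5, df=1))


def bonferroni_threshold(genomewide_alpha: float, n_phenotypes: int) -> float:
    """Per-phenotype significance threshold ``alpha / n_phenotypes``.

    With the conventional genome-wide 5.0e-8 over 70 phenotypes this gives
    7.14e-10; with the epigenome-wide 3.6e-8 it gives 5.14e-10.
    """
    if not 0.0 < genomewide_alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be at least 1")
    return genomewide_alpha / n_phenotypes


def _extract(markers) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Return (values samples x markers, marker map, is_genotype)."""
    if isinstance(markers, GenotypeMatrix):
        return markers.dosages, markers.snp_map, True
    if isinstance(markers, MethylationMatrix):
        return markers.values, markers.cpg_map, False
    raise TypeError("markers must be a GenotypeMatrix or MethylationMatrix")


def _phenotype_series(phenotype) -> pd.Series:
    if isinstance(phenotype, PreparedPhenotype):
        return phenotype.residuals
    return phenotype


def ols_scan(
    markers,
    phenotype,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker least-squares scan; returns a summary-statistics frame.

    Betas are per unit of the raw marker (per effect allele for dosages);
    two-sided p-values come from the t distribution with
    ``n - n_covariates - 2`` degrees of freedom and are clamped at 1e-320.
    Monomorphic markers are skipped with a log entry.
    """
    values, mmap, is_geno = _extract(markers)
    y = _phenotype_series(phenotype)
    idx = values.index.intersection(y.index)
    if len(idx) < len(values.index) or len(idx) < len(y.index):
        values = values.loc[idx]
        y = y.loc[idx]
    elif not values.index.equals(y.index):
        y = y.loc[values.index]
        idx = values.index
    n = len(idx)
    design = build_design(covariates, idx)
    q = design.shape[1]  # includes intercept
    if n <= q + 1:
        raise ValueError(f"too few samples (n={n}) for {q} covariate columns")

    X = values.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    W = design.to_numpy(dtype=float)
    Q, _ = np.linalg.qr(W)
    yt = yv - Q @ (Q.T @ yv)
    Xt = X - Q @ (Q.T @ X)

    sx2 = (Xt**2).sum(axis=0)
    poly = X.std(axis=0) > 0
    skipped = values.columns[~poly]
    for name in skipped:
        logger.info("ols_scan: skipping monomorphic marker %s", name)

    df = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Xt * yt[:, None]).sum(axis=0) / sx2
        rss = yt @ yt - beta * (Xt * yt[:, None]).sum(axis=0)
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sx2)
        tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df=df)
    p = np.clip(p, P_FLOOR, 1.0)

    out = pd.DataFrame(
        {
            "id": values.columns,
            "chrom": mmap["chrom"].to_numpy(),
            "pos": mmap["pos"].to_numpy(),
            "effect_allele": mmap["effect_allele"].to_numpy() if is_geno else "NA",
            "other_allele": mmap["other_allele"].to_numpy() if is_geno else "NA",
            "eaf": X.mean(axis=0) / 2.0 if is_geno else np.nan,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )[SUMSTATS_COLUMNS]
    return out[poly].reset_index(drop=True)


def stepwise_conditional(
    genotypes: GenotypeMatrix,
    phenotype,
    threshold: float,
    max_steps: int | None = None,
) -> pd.DataFrame:
    """Forward-selection conditional analysis with joint refitting.

    Repeatedly scans the phenotype conditioning on the selected markers
    (carried as covariates) and adds the most significant marker while its
    p-value passes ``threshold``; p ties break on lowest (chrom, pos).
    Returns the selected markers with betas/ses from the final joint model.
    Aborts if the selected set reaches half the sample size (pathological
    collinearity).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    y = _phenotype_series(phenotype)
    n = len(y)
    selected: list[str] = []
    while True:
        if len(selected) >= n / 2:
            raise RuntimeError(
                f"conditional selection reached {len(selected)} markers (n={n}); "
                "aborting on suspected collinearity"
            )
        cov = genotypes.dosages[selected].astype(float) if selected else None
        rest = genotypes.dosages.drop(columns=selected)
        if rest.shape[1] == 0:
            break
        stats = ols_scan(
            GenotypeMatrix(dosages=rest, snp_map=genotypes.snp_map.loc[rest.columns]),
            y,
            covariates=cov,
        )
        if len(stats) == 0:
            break
        best_p = stats["p"].min()
        if best_p >= threshold:
            break
        ties = stats[stats["p"] == best_p].sort_values(["chrom", "pos"])
        selected.append(str(ties.iloc[0]["id"]))

    if not selected:
        return pd.DataFrame(columns=SUMSTATS_COLUMNS)

    # final joint model of all selected markers
    X = genotypes.dosages[selected].to_numpy(dtype=float)
    W = np.column_stack([np.ones(n), X])
    yv = y.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(W, yv, rcond=None)
    resid = yv - W @ coef
    df = n - W.shape[1]
    sigma2 = resid @ resid / df
    cov_beta = sigma2 * np.linalg.inv(W.T @ W)
    se = np.sqrt(np.diag(cov_beta))[1:]
    beta = coef[1:]
    p = np.clip(2.0 * sps.t.sf(np.abs(beta / se), df=df), P_FLOOR, 1.0)
    mmap = genotypes.snp_map.loc[selected]
    return pd.DataFrame(
        {
            "id": selected,
            "chrom": mmap["chrom"].to_numpy(),
            "pos": mmap["pos"].to_numpy(),
            "effect_allele": mmap["effect_allele"].to_numpy(),
            "other_allele": mmap["other_allele"].to_numpy(),
            "eaf": X.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )[SUMSTATS_COLUMNS]


def _reml_variance_ratio(S: np.ndarray, Uy: np.ndarray, UW: np.ndarray) -> float:
    """Profile-REML estimate of gamma = sigma_g^2 / sigma_e^2.

    ``S`` are relatedness eigenvalues, ``Uy``/``UW`` the rotated phenotype
    and fixed-effect design.  One-dimensional optimisation on log(gamma).
    """
    n, q = UW.shape

    def neg_reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        v = gamma * S + 1.0
        w = 1.0 / v
        WtVW = UW.T @ (UW * w[:, None])
        WtVy = UW.T @ (Uy * w)
        try:
            coef = np.linalg.solve(WtVW, WtVy)
        except np.linalg.LinAlgError:
            return np.inf
        r = Uy - UW @ coef
        rss = r @ (r * w)
        sigma_e2 = rss / (n - q)
        sign, logdet_WtVW = np.linalg.slogdet(WtVW)
        if sign <= 0 or sigma_e2 <= 0:
            return np.inf
        ll = -0.5 * ((n - q) * np.log(sigma_e2) + np.log(v).sum() + logdet_WtVW + (n - q))
        return -ll

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
    return float(np.exp(res.x))


def mlm_ewas(
    methylation: MethylationMatrix,
    phenotype,
    covariates: pd.DataFrame | None = None,
    variance_ratio: float | None = None,
    relatedness: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mixed-model EWAS with a methylation-relatedness random effect.

    The relatedness matrix ``K = M M'/m`` from all standardised probes is
    fitted as a random effect by REML (one eigendecomposition, reused for
    every probe), then each probe is tested by GLS including its own
    contribution to ``K`` (MOA-like; probe coordinates in synthetic data
    carry no chromosome semantics so no leave-one-chromosome-out).
    ``variance_ratio`` fixes sigma_g^2/sigma_e^2 instead of estimating it
    (0 reduces the model to OLS); ``relatedness`` overrides ``K``.
    """
    if methylation.n_cpgs < 2 and relatedness is None:
        raise ValueError("need at least 2 probes to form a relatedness matrix")
    y = _phenotype_series(phenotype)
    values = methylation.values.loc[y.index]
    n, m = values.shape
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    poly = sd > 0
    Xs = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
    if relatedness is None:
        K = Xs @ Xs.T / Xs.shape[1]
    else:
        K = np.asarray(relatedness, dtype=float)
    K = 0.5 * (K + K.T) + 1e-8 * np.eye(n)
    S, U = np.linalg.eigh(K)
    if S.min() <= 0:
        raise ValueError("relatedness matrix is not positive definite after regularisation")

    design = build_design(covariates, values.index)
    W = design.to_numpy(dtype=float)
    q = W.shape[1]
    yv = y.to_numpy(dtype=float)
    Uy = U.T @ yv
    UW = U.T @ W

    gamma = _reml_variance_ratio(S, Uy, UW) if variance_ratio is None else float(variance_ratio)
    v = gamma * S + 1.0
    w = 1.0 / v
    # profile residual variance at the chosen ratio
    WtVW = UW.T @ (UW * w[:, None])
    coef = np.linalg.solve(WtVW, UW.T @ (Uy * w))
    r = Uy - UW @ coef
    sigma_e2 = float(r @ (r * w) / (n - q))

    UX = U.T @ X
    df = n - q - 1
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    cols = np.flatnonzero(X.std(axis=0) > 0)
    wUW = UW * w[:, None]
    A11 = UW.T @ wUW  # q x q, constant across probes
    for j in cols:
        xj = UX[:, j]
        a12 = wUW.T @ xj
        a22 = xj @ (xj * w)
        b1 = wUW.T @ Uy
        b2 = xj @ (Uy * w)
        A = np.empty((q + 1, q + 1))
        A[:q, :q] = A11
        A[:q, q] = a12
        A[q, :q] = a12
        A[q, q] = a22
        b = np.append(b1, b2)
        Ainv = np.linalg.inv(A)
        sol = Ainv @ b
        beta[j] = sol[q]
        se[j] = np.sqrt(sigma_e2 * Ainv[q, q])
    for name in values.columns[X.std(axis=0) == 0]:
        logger.info("mlm_ewas: skipping monomorphic probe %s", name)

    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(beta / se), df=df)
    p = np.clip(p, P_FLOOR, 1.0)
    mmap = methylation.cpg_map
    out = pd.DataFrame(
        {
            "id": values.columns,
            "chrom": mmap["chrom"].to_numpy(),
            "pos": mmap["pos"].to_numpy(),
            "effect_allele": "NA",
            "other_allele": "NA",
            "eaf": np.nan,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )[SUMSTATS_COLUMNS]
    return out[X.std(axis=0) > 0].reset_index(drop=True)


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median association chi-square over 0.455."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def attenuation_percent(beta_unadjusted: float, beta_adjusted: float) -> float:
    """Percent attenuation of an effect after covariate adjustment.

    ``100 * (|b_unadj| - |b_adj|) / |b_unadj|``.  If the adjusted beta is
    nonzero with opposite sign the percent is not meaningful; NaN is
    returned with a sign-flip warning instead.
    """
    if beta_unadjusted == 0:
        raise ValueError("unadjusted beta is zero; attenuation undefined")
    if beta_adjusted != 0 and np.sign(beta_adjusted) != np.sign(beta_unadjusted):
        warnings.warn("sign flip between unadjusted and adjusted betas", stacklevel=2)
        return float("nan")
    return 100.0 * (abs(beta_unadjusted) - abs(beta_adjusted)) / abs(beta_unadjusted)
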