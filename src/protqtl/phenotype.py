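"""Protein-level preparation: LOD filtering, rank-INT, residualisation.

The association stages all operate on standardised residuals: protein
abundances are filtered on detectability, forced to normality by
rank-based inverse normalisation and regressed onto technical/biological
covariates; the z-scored residuals are the phenotype.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .types import CollinearityError, PreparedPhenotype, ProteinPanel

logger = logging.getLogger(__name__)


def lod_filter(panel: ProteinPanel, max_below_frac: float = 0.40) -> ProteinPanel:
    """Drop proteins whose below-LOD fraction strictly exceeds the cutoff.

    "Over 40% below the lowest limit of detection" is read as a strict
    inequality: a protein with exactly 40% of samples below LOD is kept.
    Removals are emitted on the module logger.
    """
    frac = panel.lod_flags.mean(axis=1)
    keep = frac <= max_below_frac
    removed = panel.values.index[~keep]
    for name in removed:
        logger.info("lod_filter: removing %s (%.1f%% below LOD)", name, 100 * frac[name])
    if keep.sum() == 0:
        logger.warning("lod_filter: all proteins removed")
    return ProteinPanel(
        values=panel.values.loc[keep],
        lod_flags=panel.lod_flags.loc[keep],
        protein_map=panel.protein_map.loc[panel.protein_map.index.intersection(panel.values.index[keep])],
    )


def rank_inverse_normal(values, offset: str = "half") -> np.ndarray | pd.Series:
    """Rank-based inverse normal transform.

    Ranks (ties averaged) are mapped through the standard normal quantile
    function at ``(rank - 0.5)/n`` (``offset="half"``, the default) or the
    Blom convention ``(rank - 3/8)/(n + 1/4)``.  Missing values propagate
    and do not consume ranks.  The result depends on the input only
    through its ranks, so the transform is invariant to any strictly
    monotone transformation.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    x = arr[mask]
    if x.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("all-constant input: ranks are undefined")
    ranks = rankdata(x, method="average")
    n = x.size
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset convention {offset!r}")
    out[mask] = ndtri(q)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def build_design(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    """Expand a covariate table into a numeric design matrix with intercept.

    Categorical/object columns become treatment-coded indicators (first
    level dropped); numeric columns pass through unchanged.
    """
    design = pd.DataFrame({"intercept": 1.0}, index=index)
    if covariates is None or covariates.shape[1] == 0:
        return design
    cov = covariates.loc[index]
    cat_cols = [
        c
        for c in cov.columns
        if isinstance(cov[c].dtype, pd.CategoricalDtype) or cov[c].dtype == object
    ]
    expanded = pd.get_dummies(cov, columns=cat_cols, drop_first=True, dtype=float)
    return pd.concat([design, expanded.astype(float)], axis=1)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name columns whose removal restores full rank
    culprits = []
    for j, col in enumerate(design.columns):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            culprits.append(col)
    raise CollinearityError(f"rank-deficient covariate matrix; collinear columns: {culprits}")


def residualize(values: pd.Series, covariates: pd.DataFrame | None = None) -> PreparedPhenotype:
    """OLS-residualise a phenotype on covariates and z-score the result.

    Samples with a missing phenotype are dropped (and recorded); missing
    covariate values among retained samples raise.  A perfect covariate
    fit (zero residual variance) raises rather than returning NaNs.
    """
    missing = values.index[values.isna()]
    kept = values.dropna()
    design = build_design(covariates, kept.index)
    if design.isna().to_numpy().any():
        raise ValueError("missing covariate values for retained samples")
    _check_full_rank(design)
    X = design.to_numpy(dtype=float)
    y = kept.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std()
    if sd < 1e-10:
        raise ValueError("zero residual variance: phenotype is fully explained by covariates")
    resid = (resid - resid.mean()) / sd
    return PreparedPhenotype(
        residuals=pd.Series(resid, index=kept.index, name=values.name),
        covariates_used=list(design.columns),
        dropped_samples=[str(s) for s in missing],
    )
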