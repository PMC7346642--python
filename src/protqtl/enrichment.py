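"""Hypergeometric over-representation of hit genes against gene sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit annotation universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate gene ids in set {name!r}")
            stray = set(genes) - uni
            if stray:
                raise ValueError(f"set {name!r} contains genes outside the universe: {sorted(stray)[:5]}")


def hypergeom_enrich(
    hit_genes,
    collection: GeneSetCollection,
    correction: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment, P(X >= overlap), per gene set.

    The population is the annotation universe, successes are the set's
    genes, draws are the hit genes.  Hits outside the universe are dropped
    with a warning.  ``correction`` is "bonferroni" or "bh"
    (Benjamini-Hochberg) across the tested sets.
    """
    uni = set(collection.universe)
    if not uni:
        raise ValueError("empty universe")
    hits = [g for g in dict.fromkeys(hit_genes)]  # dedupe, keep order
    stray = [g for g in hits if g not in uni]
    if stray:
        logger.warning("hypergeom_enrich: dropping %d hit genes outside the universe", len(stray))
        hits = [g for g in hits if g in uni]
    if not hits:
        raise ValueError("no hit genes within the universe")

    N = len(uni)
    n_draw = len(hits)
    hit_set = set(hits)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(hit_set & set(genes))
        p = float(hypergeom.sf(k - 1, N, K, n_draw))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "expected": n_draw * K / N,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r}")
    table["p_adjusted"] = multipletests(table["p"], method=method)[1]
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)
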