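# protqtl

Multi-method genome- and epigenome-wide analysis of plasma protein
levels: who controls the circulating inflammatory proteome, common
genetic variation or DNA methylation — and how much of each?

`protqtl` is a desk-scale, fully tested re-implementation of that
analysis style for multiplex protein panels (Olink-like NPX values)
measured alongside SNP genotypes and array methylation in the same
individuals. It provides:

- **Phenotype preparation** — limit-of-detection filtering, rank-based
  inverse normalisation, covariate residualisation to standardised
  residuals.
- **Marginal scans** — per-SNP/per-CpG OLS with Bonferroni thresholds
  (5.0e-8/70 = 7.14e-10 for SNPs, 3.6e-8/70 = 5.14e-10 for CpGs),
  forward conditional selection, a mixed-model EWAS with a
  methylation-relatedness random effect, genomic inflation λ, and
  smoking-attenuation arithmetic.
- **A grouped spike-and-slab Bayesian mixture model** (the core): all
  SNPs and all CpGs fitted jointly by Gibbs sampling under per-marker
  priors `π_0 δ_0 + Σ_k π_k N(0, c_k σ²_g)` with slab variances
  c = (0.01, 0.1) for SNPs, (0.001, 0.01, 0.1) for CpGs and
  (0.01, 0.1, 0.2) for the combined run; outputs per-marker posterior
  inclusion probabilities (significant at PIP ≥ 0.95) and per-group
  variance shares `var(X_g β_g)/var(y)` with 95% credible intervals and
  per-component attribution.
- **Triangulation** — concordance of hits across methods directly or
  through LD proxies (r² > 0.75), cis/trans classification at a 10 Mb
  TSS window, effect-size correlation with Fisher-z intervals.
- **Causal follow-up** — approximate-Bayes-factor colocalisation over
  ±200 kb regions (five hypotheses, PP ≥ 0.95 as strong evidence) and
  two-sample Mendelian randomisation (LD-pruned instruments at
  r² < 0.1; Wald ratio, IVW, MR-Egger intercept).
- **Enrichment** — hypergeometric over-representation of hit genes
  against GMT gene sets.
- **Synthetic cohorts** — generators for genotypes with block LD,
  methylation with cell-composition/batch/smoking structure, proteins
  built from mixture-distributed effects with recorded ground truth,
  and paired regional summary statistics for coloc scenarios.

Real cohort data of this kind are typically access-restricted; the
package is exercised end-to-end on synthetic cohorts whose architecture
is known exactly, so every estimate can be checked against truth.

## Worked example

```python
import pandas as pd
from protqtl.simulate import (ArchitectureConfig, simulate_genotypes,
                              simulate_methylation, simulate_proteins)
from protqtl.bayesr import (ChainConfig, MixturePrior, OmicsGroup,
                            SNP_PRIOR_VARIANCES, CPG_PRIOR_VARIANCES,
                            fit_bayes_mixture, variance_partition)
from protqtl.types import standardize_columns

geno = simulate_genotypes(1000, 2000, ld_block_size=5, seed=1)
meth, covariates, _ = simulate_methylation(1000, 2000, seed=2)
protein, truth = simulate_proteins(
    geno, meth, covariates,
    ArchitectureConfig(h2_genetic=0.30, h2_methylation=0.20,
                       n_causal_snps=10, n_causal_cpgs=10),
    seed=3)

groups = [
    OmicsGroup("genetics", standardize_columns(
        geno.dosages.astype(float).loc[:, geno.dosages.std(ddof=0) > 0])),
    OmicsGroup("methylation", standardize_columns(meth.values)),
]
post = fit_bayes_mixture(
    groups, protein,
    priors={"genetics": MixturePrior(SNP_PRIOR_VARIANCES),
            "methylation": MixturePrior(CPG_PRIOR_VARIANCES)},
    chain=ChainConfig(n_iterations=2200, burn_in=1000, thinning=2, seed=4))
print(variance_partition(post)[["group", "mean_share", "ci_low", "ci_high"]])
```

prints (seed-for-seed):

```
         group  mean_share    ci_low   ci_high
0     genetics    0.292005  0.244466  0.347221
1  methylation    0.234961  0.179846  0.288971
```

The genetic group's posterior mean share (0.29) and the methylation
share (0.23) recover the generating truth of 0.30/0.20, and both 95%
credible intervals cover it — the same reading one would give real
heritability and methylation-variance estimates from this model.

A thin CLI wraps the same functions
(`protqtl simulate | prep | gwas-ols | ewas-ols | ewas-mlm | bayes-fit |
concord | coloc | mr | enrich | report`); every run writes a JSON
provenance record with seeds and input checksums.

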