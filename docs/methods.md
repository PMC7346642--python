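# Methods

## The problem

Plasma levels of inflammatory proteins vary widely between individuals.
Two molecular data types measured in the same cohort — SNP genotypes and
blood DNA methylation — each explain part of that variation, and the
scientific questions are (i) which individual markers are associated
with each protein, robustly across statistical methods, and (ii) what
fraction of each protein's variance the two data types explain, alone
and jointly. `protqtl` implements the full analysis path: phenotype
preparation, marginal and conditional scans, a joint Bayesian
variance-partitioning model, cross-method triangulation, and causal
follow-up (colocalisation, Mendelian randomisation), all exercised on
synthetic cohorts with recorded ground truth.

## Phenotype preparation

Proteins with more than 40% of samples below the assay's lowest limit of
detection are removed (strictly greater than — a protein at exactly 40%
is kept). Retained values are transformed by rank-based inverse
normalisation: ranks (ties averaged) are mapped through the standard
normal quantile at `(rank − 0.5)/n`. The offset convention matters only
in the extreme tails; the Blom variant `(rank − 3/8)/(n + 1/4)` is
selectable in configuration. The transformed values are residualised on
covariates (age, sex, ancestry PCs, array plate in a real cohort;
whatever table is supplied here) by OLS with categorical covariates
expanded to treatment-coded indicators, and the residuals are z-scored.
Rank-deficient designs raise an error naming the collinear columns, and
a perfect covariate fit (zero residual variance) raises rather than
emitting NaNs. Plate-style batch covariates are treated as fixed
indicators, not random effects.

## Marginal scans

Per-marker OLS uses the Frisch–Waugh–Lovell decomposition: one QR
projection removes the covariates from the phenotype and all markers,
then each marker is a simple regression on the residualised data. Betas
are per effect allele (or per unit methylation); p-values come from the
t distribution at `n − q − 1` degrees of freedom and are clamped at
1e-320 to avoid underflow to zero. Significance thresholds divide a
genome-wide alpha by the number of phenotypes: 5.0e-8/70 = 7.14e-10 for
SNPs and 3.6e-8/70 = 5.14e-10 for CpGs.

Conditional analysis is forward selection at the same threshold: scan,
add the most significant marker to the covariate set, rescan, stop when
nothing passes; p ties break on lowest (chrom, pos), which also makes
the output invariant to marker column order. Reported effects come from
one final joint model of all selected markers. Selection aborts if it
reaches n/2 markers (pathological collinearity).

The mixed-model EWAS fits a methylation-relatedness random effect
`K = M M'/m` over all standardised probes by REML — a single
eigendecomposition of K, a one-dimensional profile-likelihood search
over the variance ratio, then per-probe GLS reusing the rotation. The
candidate probe's own contribution to K is not removed (probe
coordinates in synthetic data carry no chromosome semantics, so no
leave-one-chromosome-out). A `variance_ratio=0` override reduces the
model to OLS exactly, which the tests exploit.

Genomic inflation is `λ = median(χ²)/0.4549`, with the association χ²
obtained from p by the inverse χ²₁ survival function. Attenuation after
adding a covariate is `100·(|b_unadj| − |b_adj|)/|b_unadj|`; when the
adjusted effect flips sign the percentage is meaningless, so the
function returns NaN with a warning instead.

## The grouped spike-and-slab mixture model

The core model regresses the standardised phenotype jointly on one or
two column-standardised marker groups:

    y = W a + Σ_g X_g β_g + ε,
    β_gj ~ π_g0 δ_0 + Σ_k π_gk N(0, c_gk σ²_g),   ε ~ N(0, σ²_ε I).

Slab constants are c = (0.01, 0.1) for a stand-alone SNP run,
(0.001, 0.01, 0.1) for CpGs, and (0.01, 0.1, 0.2) for both groups in
the combined run (the two groups use identical vectors there). The
constants are interpreted as fractions multiplying the sampled group
hyperparameter σ²_g; a configuration flag switches to fixed absolute
slab variances instead, which is also how the exact-enumeration oracle
test pins the model down.

One Gibbs sweep: (1) fixed-effect coefficients from their conditional
normal (flat prior); (2) each marker in a freshly randomised order —
form the partial residual, compute spike-vs-slab posterior odds per
component, sample the indicator, then the effect; (3) mixture
proportions per group from Dirichlet(counts + concentration), with
concentration 1 (uninformative) by default; (4) σ²_g per group and (5)
σ²_ε from scaled inverse-χ² conditionals with weakly informative
ν₀ = s₀² = 0.001; (6) record the draw past burn-in on the thinning
stride. The reference chain length is 10 000 iterations with 5 000
burn-in and thinning of 5 (1 000 retained draws); shorter chains are
used in tests (sizes below). The marker loop is compiled with numba and
maintains the residual and per-component fitted vectors incrementally,
so a sweep costs O(n·m); one seed drives all randomness and retained
draws are bit-reproducible.

Variance shares are computed per retained draw as
`var(X_g β_g)/var(y)` on the analysis sample — sample-specific and
bounded — with 95% credible intervals from the 2.5th/97.5th percentiles
of the draws. Attribution of a group's share to slab component k is
`cov(u_k, u_total)/var(y)` where `u_k` is the fitted contribution of
markers currently in component k; this covariance allocation sums
exactly to the group share within every draw (a plain `var(u_k)` sum
would not, because of cross-component covariance). Markers are
significant at posterior inclusion probability ≥ 0.95 (inclusive).
Welch t-tests compare the share draws of a "data type alone" fit with
its draws conditional on the other data type.

Fixed covariates are handled by explicit coefficient sampling inside
the chain, not pre-residualisation, so a combined run can carry cell
proportions and smoking alongside both marker groups.

## Triangulation and causal follow-up

A marker is concordant across methods if every hit set contains it
directly or through a proxy in LD r² > 0.75 (computed on the analysis
sample's dosages; no reference panel). Cis means within 10 Mb of the
encoding gene's TSS, inclusive at the boundary ("within 10 Mb"); any
cross-chromosome pair is trans.

Colocalisation summarises each SNP by the Wakefield approximate Bayes
factor `log ABF = 0.5(log(1−r) + r z²)`, `r = W/(V+W)`, with prior
effect sd 0.15 per quantitative trait, and assembles the five hypothesis
weights with per-SNP priors p1 = p2 = 1e-4, p12 = 1e-5 over a ±200 kb
region. All accumulation is log-space (log-sum-exp; the H3 cross term
uses a guarded log-difference), so posteriors remain finite for |z|
well beyond 50. Swapping traits swaps PP1/PP2 and fixes the rest.

MR instruments are LD-pruned greedily in ascending p order at
r² < 0.1, so the sentinel variant always survives. Harmonisation flips
outcome betas when effect alleles are swapped and drops strand-ambiguous
A/T and C/G variants (a conservative choice; they cannot be oriented
without frequency information). The Wald ratio uses the first-order
delta-method se (`se_out/|b_exp|`), accurate for strong instruments and
verified against Monte Carlo; IVW is fixed-effect WLS through the
origin with weights 1/se_out²; MR-Egger adds an intercept (exposure
betas oriented non-negative) whose p-value tests directional
pleiotropy.

Gene-set enrichment is the upper-tail hypergeometric `P(X ≥ k)` over an
explicit annotation universe, with Bonferroni or Benjamini-Hochberg
adjustment across the tested sets.

## The synthetic cohorts

The generators produce the structure the analysis assumes, nothing
more.

- **Genotypes**: within an LD block all SNPs share one allele frequency
  (drawn uniformly from the MAF range) and each haplotype allele copies
  the previous SNP's allele with probability `ld_decay`, else is
  redrawn — first-order Markov copying, the simplest mechanism giving
  tunable r² while preserving the marginal MAF exactly. Blocks are
  independent; there is no recombination map, imputation or population
  structure.
- **Methylation**: each probe is intercept + cell-proportion loadings +
  batch shift + (for designated probes) a smoking effect + unit
  Gaussian noise, on a continuous unbounded M-value-like scale. No
  [0,1] beta-value constraint is enforced since every downstream step
  standardises columns. Cell proportions are Dirichlet with a dominant
  type; the default smoking effect of −2.0 on about 1% of probes
  mirrors the magnitude of the strongest smoking-reactive probes on
  methylation arrays.
- **Proteins**: causal markers are drawn per mixture-class proportions,
  raw effects from the corresponding Gaussian, and each component is
  rescaled on its realised (empirical) variance to hit the target
  share; the noise is empirically orthogonalised against the
  genetic/methylation/confounder parts and scaled so `var(y) = 1`
  exactly. Realised shares therefore equal the recorded ground truth by
  construction, which makes recovery tests sharp. Smoking can act on
  both designated probes and the protein itself, reproducing the
  confounding that drives the attenuation analysis. Protein noise is
  Gaussian; rank-INT makes the pre-transformation distribution
  immaterial downstream.
- **Summary pairs**: two traits are simulated at the individual level
  from one genotype pool (so beta, se and p are internally consistent)
  and summarised by the OLS scan; scenarios place the causal variant in
  both traits, in low-LD distinct positions, in one trait, or nowhere.
  The causal effect is sized so the expected sentinel z-score is 12 by
  default.

What passing tests on these cohorts do **not** show: robustness to
realistic human LD, rare variants, probe cross-hybridisation, batch
confounding correlated with the phenotype, or non-Gaussian assay noise.

## Numerical choices and test problem sizes

Degenerate inputs raise early: monomorphic markers are skipped with a
log entry in scans but are an error in LD computations; non-standardised
group columns are rejected by the Bayesian fit (tolerance 1e-6 on the
mean, 1e-4 on the variance) rather than silently rescaled. p-values are
floored at 1e-320 everywhere, including on file write (with a warning).
σ²_g is clamped to [1e-12, 1e8] to keep the empty-model state finite.

Test and acceptance runs use desk-scale problem sizes chosen to finish
in minutes on one CPU while keeping the study's generating conditions:
the two-group recovery runs n = 1000 with 2000 SNPs + 2000 CpGs and
true shares 0.30/0.20 over 6 (tests) or 4 (acceptance script) seeds
with 2200-iteration chains (600 retained draws); the single-variant
case runs n = 876 with a 36% variance share over 8 and 6 seeds; the
two-marker sampler-vs-enumeration oracle uses 50 000 draws; scenario and
calibration suites use 50–200 summary-level replicates. Recovery
tolerances (±0.08 on posterior-mean shares, ≥ 85% CI coverage,
PIP > 0.95 in ≥ 90% of seeds) are unchanged from the full-size design.

## Known limitations

Single-chain inference without formal convergence diagnostics (the
reference chain settings are generous for the tested problem sizes);
no GxE or interaction terms; covariance-based component attribution can
in principle go slightly negative for a component whose fitted vector
anticorrelates with the group total; the mixed model assumes one global
variance ratio for all probes; MR implements Wald/IVW/Egger only (no
weighted-median or MR-PRESSO).
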