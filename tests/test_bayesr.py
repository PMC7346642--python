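"""Spike-and-slab sampler: recovery, oracle equivalence, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from protqtl.bayesr import (
    CPG_PRIOR_VARIANCES,
    ChainConfig,
    MixturePrior,
    OmicsGroup,
    SNP_PRIOR_VARIANCES,
    compare_variance_posteriors,
    fit_bayes_mixture,
    significant_markers,
    variance_partition,
)
from protqtl.simulate import (
    ArchitectureConfig,
    simulate_genotypes,
    simulate_methylation,
    simulate_proteins,
)
from protqtl.types import standardize_columns


def _std_genotype_group(geno, name="genetics"):
    dos = geno.dosages.astype(float)
    dos = dos.loc[:, dos.std(ddof=0) > 0]
    return OmicsGroup(name, standardize_columns(dos))


def _series(y):
    return pd.Series(np.asarray(y, float) if not isinstance(y, pd.Series) else y)


class TestChainConfig:
    def test_retained_draw_arithmetic(self):
        chain = ChainConfig(n_iterations=10_000, burn_in=5_000, thinning=5)
        assert chain.retained_draws == 1000

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thinning=0)


class TestMixturePrior:
    def test_variances_must_increase(self):
        with pytest.raises(ValueError):
            MixturePrior((0.1, 0.01))

    def test_scalar_concentration_broadcast(self):
        prior = MixturePrior((0.01, 0.1), dirichlet_concentration=1.0)
        assert prior.dirichlet_concentration == (1.0, 1.0, 1.0)


class TestFitValidation:
    def test_non_standardized_group_rejected(self, rng):
        vals = pd.DataFrame(rng.normal(2.0, 3.0, size=(50, 5)))
        y = pd.Series(rng.normal(size=50))
        with pytest.raises(ValueError, match="standardised"):
            fit_bayes_mixture([OmicsGroup("g", vals)], y,
                              chain=ChainConfig(n_iterations=200, burn_in=100, thinning=1))

    def test_few_retained_draws_warns(self, rng):
        vals = standardize_columns(pd.DataFrame(rng.normal(size=(50, 5))))
        y = pd.Series(rng.normal(size=50))
        with pytest.warns(UserWarning, match="retained draws"):
            fit_bayes_mixture([OmicsGroup("g", vals)], y,
                              chain=ChainConfig(n_iterations=110, burn_in=100, thinning=1))


@pytest.fixture(scope="module")
def null_fit():
    geno = simulate_genotypes(300, 1000, ld_block_size=1, seed=51)
    rng = np.random.default_rng(52)
    y = pd.Series(rng.normal(size=300), index=geno.dosages.index)
    y = (y - y.mean()) / y.std(ddof=0)
    chain = ChainConfig(n_iterations=1500, burn_in=500, thinning=2, seed=53)
    return fit_bayes_mixture(
        [_std_genotype_group(geno)], y,
        priors={"genetics": MixturePrior(SNP_PRIOR_VARIANCES)}, chain=chain,
    )


class TestNullBehaviour:
    def test_no_marker_reaches_pip_threshold(self, null_fit):
        assert (null_fit.markers["pip"] < 0.95).all()

    def test_share_interval_reaches_down_to_small_values(self, null_fit):
        vp = variance_partition(null_fit).iloc[0]
        assert vp["ci_low"] <= 0.05

    def test_pi_draws_are_probability_vectors(self, null_fit):
        pi = null_fit.pi_draws["genetics"]
        assert np.allclose(pi.sum(axis=1), 1.0, atol=1e-12)
        assert (pi >= 0).all()

    def test_pips_in_unit_interval(self, null_fit):
        assert ((null_fit.markers["pip"] >= 0) & (null_fit.markers["pip"] <= 1)).all()


@pytest.fixture(scope="module")
def fit_and_truth():
    geno = simulate_genotypes(876, 400, ld_block_size=1, seed=61)
    sim = simulate_methylation(876, 5, seed=62)
    y, arch = simulate_proteins(
        geno, sim.methylation, sim.covariates,
        ArchitectureConfig(h2_genetic=0.36, h2_methylation=0.0,
                           n_causal_snps=1, n_causal_cpgs=0),
        seed=63,
    )
    chain = ChainConfig(n_iterations=1600, burn_in=600, thinning=2, seed=64)
    post = fit_bayes_mixture(
        [_std_genotype_group(geno)], y,
        priors={"genetics": MixturePrior(SNP_PRIOR_VARIANCES)}, chain=chain,
    )
    return post, arch


class TestSingleSnpRecovery:
    def test_causal_snp_pip_high(self, fit_and_truth):
        post, arch = fit_and_truth
        pip = post.markers.set_index("id").loc[arch.causal_snp_ids[0], "pip"]
        assert pip > 0.95

    def test_share_ci_covers_truth(self, fit_and_truth):
        post, arch = fit_and_truth
        vp = variance_partition(post).iloc[0]
        assert vp["ci_low"] <= arch.true_h2_genetic <= vp["ci_high"]
        assert abs(vp["mean_share"] - 0.36) < 0.08

    def test_reproducible_given_seed(self, fit_and_truth):
        post, arch = fit_and_truth
        geno = simulate_genotypes(876, 400, ld_block_size=1, seed=61)
        sim = simulate_methylation(876, 5, seed=62)
        y, _ = simulate_proteins(
            geno, sim.methylation, sim.covariates,
            ArchitectureConfig(h2_genetic=0.36, h2_methylation=0.0,
                               n_causal_snps=1, n_causal_cpgs=0),
            seed=63,
        )
        chain = ChainConfig(n_iterations=1600, burn_in=600, thinning=2, seed=64)
        again = fit_bayes_mixture(
            [_std_genotype_group(geno)], y,
            priors={"genetics": MixturePrior(SNP_PRIOR_VARIANCES)}, chain=chain,
        )
        assert np.array_equal(post.share_draws.to_numpy(), again.share_draws.to_numpy())
        assert np.array_equal(post.markers["pip"], again.markers["pip"])


class TestSignificantMarkers:
    def _posterior_with_pips(self, null_fit, pips):
        post = null_fit
        post.markers.loc[: len(pips) - 1, "pip"] = pips
        return post

    def test_inclusive_threshold(self, null_fit):
        post = self._posterior_with_pips(null_fit, [0.95, 0.3])
        hits = significant_markers(post, pip_threshold=0.95)
        assert post.markers.iloc[0]["id"] in set(hits["id"])

    def test_threshold_zero_returns_all(self, null_fit):
        assert len(significant_markers(null_fit, pip_threshold=0.0)) == len(null_fit.markers)

    def test_sorted_by_pip_descending(self, null_fit):
        hits = significant_markers(null_fit, pip_threshold=0.0)
        assert (np.diff(hits["pip"]) <= 0).all()


class TestVariancePartition:
    def test_component_attribution_sums_to_share_per_draw(self, null_fit):
        comp = null_fit.comp_share_draws["genetics"]
        total = null_fit.share_draws["genetics"].to_numpy()
        assert np.allclose(comp.sum(axis=1), total, atol=1e-10)

    def test_shares_bounded(self, null_fit):
        draws = null_fit.share_draws.to_numpy()
        assert (draws >= 0).all() and (draws <= 1).all()


def _brute_force_pips(X, y, slab_var, s2e, conc):
    """Exact posterior inclusion probabilities for a 2-marker model.

    Enumerates the 4 spike/slab configurations; the mixture weight prior
    is integrated analytically (Dirichlet-multinomial over configuration
    size) and the marginal likelihood of each configuration is the
    zero-mean multivariate normal with covariance s2e*I + slab_var*X_S X_S'.
    """
    n, m = X.shape
    assert m == 2
    log_w = {}
    for cfg in itertools.product([0, 1], repeat=m):
        k = sum(cfg)
        # Dirichlet(conc, conc) integrated Bernoulli-profile prior
        from scipy.special import gammaln

        log_prior = gammaln(conc + k) + gammaln(conc + m - k) - gammaln(2 * conc + m)
        cov = s2e * np.eye(n)
        for j, z in enumerate(cfg):
            if z:
                cov += slab_var * np.outer(X[:, j], X[:, j])
        log_like = sps.multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        log_w[cfg] = log_prior + log_like
    mx = max(log_w.values())
    w = {cfg: np.exp(v - mx) for cfg, v in log_w.items()}
    tot = sum(w.values())
    pips = np.zeros(m)
    for cfg, weight in w.items():
        for j, z in enumerate(cfg):
            if z:
                pips[j] += weight / tot
    return pips


def test_sampler_matches_brute_force_enumeration():
    """Two markers, one slab, flat Dirichlet, fixed variances: the chain's
    inclusion probabilities must agree with exact enumeration."""
    rng = np.random.default_rng(71)
    n = 60
    X = rng.normal(size=(n, 2))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.array([0.4, 0.0])
    y = X @ beta + rng.normal(0, 0.8, size=n)
    y = y - y.mean()
    s2e = float(y.var())
    slab = 0.1  # absolute slab variance with sigma2_g pinned at 1

    exact = _brute_force_pips(X, y, slab, s2e, conc=1.0)

    frame = pd.DataFrame(X, columns=["m1", "m2"])
    post = fit_bayes_mixture(
        [OmicsGroup("g", frame)],
        pd.Series(y),
        priors={"g": MixturePrior((slab,), dirichlet_concentration=1.0)},
        chain=ChainConfig(n_iterations=50_000, burn_in=2_000, thinning=1, seed=72),
        include_intercept=False,
        variance_scaling="absolute",
        update_hyperparams=False,
        sigma2_e_init=s2e,
    )
    sampled = post.markers["pip"].to_numpy()
    assert np.abs(sampled - exact).max() < 0.03


@pytest.fixture(scope="module")
def two_group_fit():
    geno = simulate_genotypes(700, 600, ld_block_size=5, seed=81)
    sim = simulate_methylation(700, 600, seed=82)
    y, arch = simulate_proteins(
        geno, sim.methylation, sim.covariates,
        ArchitectureConfig(h2_genetic=0.30, h2_methylation=0.20,
                           n_causal_snps=10, n_causal_cpgs=10),
        seed=83,
    )
    groups = [
        _std_genotype_group(geno),
        OmicsGroup("methylation", standardize_columns(sim.methylation.values)),
    ]
    priors = {
        "genetics": MixturePrior(SNP_PRIOR_VARIANCES),
        "methylation": MixturePrior(CPG_PRIOR_VARIANCES),
    }
    chain = ChainConfig(n_iterations=2200, burn_in=1000, thinning=2, seed=84)
    post = fit_bayes_mixture(groups, y, priors=priors, chain=chain)
    return post, arch, groups, priors, y


class TestTwoGroupPartition:
    def test_posterior_means_near_truth(self, two_group_fit):
        post, arch, *_ = two_group_fit
        vp = variance_partition(post).set_index("group")
        assert abs(vp.loc["genetics", "mean_share"] - arch.true_h2_genetic) < 0.08
        assert abs(vp.loc["methylation", "mean_share"] - arch.true_h2_methylation) < 0.08

    def test_group_order_exchangeable(self, two_group_fit):
        post, arch, groups, priors, y = two_group_fit
        chain = ChainConfig(n_iterations=2200, burn_in=1000, thinning=2, seed=84)
        swapped = fit_bayes_mixture(groups[::-1], y, priors=priors, chain=chain)
        a = variance_partition(post).set_index("group")["mean_share"]
        b = variance_partition(swapped).set_index("group")["mean_share"]
        assert abs(a["genetics"] - b["genetics"]) < 0.02
        assert abs(a["methylation"] - b["methylation"]) < 0.02


def test_conditional_estimates_stable_for_independent_effects():
    """With independent genetic and methylation effects, the methylation
    share estimated alone should match its estimate conditional on SNPs."""
    close = 0
    reps = 5
    for rep in range(reps):
        geno = simulate_genotypes(500, 300, ld_block_size=5, seed=900 + rep)
        sim = simulate_methylation(500, 300, seed=920 + rep)
        y, arch = simulate_proteins(
            geno, sim.methylation, sim.covariates,
            ArchitectureConfig(h2_genetic=0.25, h2_methylation=0.2,
                               n_causal_snps=8, n_causal_cpgs=8),
            seed=940 + rep,
        )
        meth_group = OmicsGroup("methylation", standardize_columns(sim.methylation.values))
        chain = ChainConfig(n_iterations=1400, burn_in=600, thinning=2, seed=960 + rep)
        alone = fit_bayes_mixture(
            [meth_group], y,
            priors={"methylation": MixturePrior(CPG_PRIOR_VARIANCES)}, chain=chain,
        )
        both = fit_bayes_mixture(
            [_std_genotype_group(geno), meth_group], y,
            priors={"genetics": MixturePrior(SNP_PRIOR_VARIANCES),
                    "methylation": MixturePrior(CPG_PRIOR_VARIANCES)},
            chain=chain,
        )
        diff = abs(
            alone.share_draws["methylation"].mean() - both.share_draws["methylation"].mean()
        )
        close += diff < 0.05
    assert close >= 0.8 * reps


class TestCompareVariancePosteriors:
    def test_identical_vectors(self):
        draws = np.full(100, 0.3)
        assert compare_variance_posteriors(draws, draws) == (0.0, 1.0)

    def test_large_shift_detected(self, rng):
        a = rng.normal(0.3, 0.02, size=500)
        b = a + 5 * 0.02
        _, p = compare_variance_posteriors(a, b)
        assert p < 1e-6

    def test_p_uniform_under_null(self, rng):
        pvals = []
        for _ in range(200):
            a = rng.normal(0.3, 0.05, size=60)
            b = rng.normal(0.3, 0.05, size=60)
            pvals.append(compare_variance_posteriors(a, b)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_draws_raise(self):
        with pytest.raises(ValueError):
            compare_variance_posteriors(np.zeros(10), np.zeros(100))
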