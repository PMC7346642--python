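import numpy as np
import pandas as pd
import pytest

from protqtl.simulate import (
    ArchitectureConfig,
    simulate_genotypes,
    simulate_methylation,
    simulate_proteins,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A shared small cohort: genotypes, methylation + covariates, protein."""
    geno = simulate_genotypes(400, 200, seed=11)
    sim = simulate_methylation(400, 150, seed=12)
    protein, arch = simulate_proteins(
        geno,
        sim.methylation,
        sim.covariates,
        ArchitectureConfig(
            h2_genetic=0.25,
            h2_methylation=0.15,
            n_causal_snps=5,
            n_causal_cpgs=5,
        ),
        seed=13,
    )
    return {
        "genotypes": geno,
        "methylation": sim.methylation,
        "covariates": sim.covariates,
        "smoking_probes": sim.smoking_probes,
        "protein": protein,
        "architecture": arch,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
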