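import numpy as np
import pytest

from apatwas.simdata import GenotypeMatrix, SimTruth, Variant, sim_genotypes, simulate_study


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    return sim_genotypes(100, 20, maf_range=(0.1, 0.5), ld_rho=0.4, seed=7)


@pytest.fixture
def small_study():
    """3 genes x 30 samples with coverage profiles and GWAS sumstats."""
    return simulate_study(
        n_genes=3, n_samples=30, m_per_gene=10, ld_rho=0.5, h2=0.3,
        make_coverage=True, make_sumstats=True, causal_gene=0, alpha=0.3,
        depth=80.0, dispersion=0.02, seed=11,
    )


@pytest.fixture
def single_gene_truth():
    return SimTruth(
        causal_idx=[np.array([0])],
        beta=[np.array([0.1])],
        baseline=np.array([0.5]),
        breakpoint=np.array([200]),
        utr_length=np.array([400]),
        noise_sd=np.array([0.1]),
        seed=1,
    )
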