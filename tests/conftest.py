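import numpy as np
import pytest

from irsqtl.genetics import impute_mean, kinship, pca
from irsqtl.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small structured cohort reused across read-only tests."""
    cfg = CohortConfig(n_samples=60, n_snps=300, n_clusters=20,
                       n_extra_genes=5, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_context(small_cohort):
    """Imputed genotypes, kinship and PCs for the small cohort."""
    G = impute_mean(small_cohort.G)
    K = small_cohort.K
    pcs = pca(K, 10).scores
    return G, K, pcs


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
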