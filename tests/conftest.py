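import numpy as np
import pytest

import poda


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small null dataset shared by read-only tests."""
    truth = poda.null_preset(
        7, n_samples=80, n_snps=400, n_genes=80, n_pathways=12, pathway_size_range=(5, 15)
    )
    return poda.generate_dataset(truth)


@pytest.fixture(scope="session")
def tiny_universe(tiny_dataset):
    g, _ = poda.filter_snps(tiny_dataset.genotypes)
    u = poda.build_universe(g, tiny_dataset.snp_gene_map, tiny_dataset.pathway_db)
    return g, u


def random_genotypes(rng, n_samples, n_snps, missing_rate=0.0, prefix="rs"):
    """Ad-hoc HWE-free random dosage matrix for fixture construction."""
    maf = rng.uniform(0.1, 0.5, size=n_snps)
    d = rng.binomial(2, maf, size=(n_samples, n_snps)).astype(float)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = np.nan
    return poda.GenotypeMatrix.from_dosage(
        [f"S{i}" for i in range(n_samples)],
        [f"{prefix}{j}" for j in range(n_snps)],
        d,
    )
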