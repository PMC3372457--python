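import numpy as np
import pytest

from genemdr.data_io import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_genotype_matrix(rng, n_samples, n_snps, case_fraction=0.5):
    """Random genotypes (HWE at random MAFs) with a random phenotype."""
    mafs = rng.uniform(0.1, 0.5, size=n_snps)
    calls = rng.binomial(2, mafs, size=(n_samples, n_snps)).astype(np.int8)
    n_case = max(1, int(round(case_fraction * n_samples)))
    phen = np.zeros(n_samples, dtype=np.int8)
    phen[rng.choice(n_samples, size=n_case, replace=False)] = 1
    return GenotypeMatrix(
        samples=[f"S{i:04d}" for i in range(n_samples)],
        snp_ids=[f"snp{j:03d}" for j in range(n_snps)],
        chrom=["1"] * n_snps,
        pos=np.arange(1, n_snps + 1) * 1000,
        calls=calls,
        phenotype=phen,
    )


@pytest.fixture
def toy_matrix(rng):
    return random_genotype_matrix(rng, 60, 4)
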