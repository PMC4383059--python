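import numpy as np
import pytest

from episcan import GenotypeMatrix, MISSING


def make_random_gm(
    m: int,
    n: int,
    seed: int,
    missing_rate: float = 0.0,
    case_fraction: float = 0.5,
) -> GenotypeMatrix:
    """Random unstructured genotype matrix (no LD), for mechanical tests."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, size=(m, n)).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random((m, n)) < missing_rate] = MISSING
    n_cases = max(1, min(n - 1, int(round(case_fraction * n))))
    pheno = np.zeros(n, dtype=np.int8)
    pheno[rng.choice(n, size=n_cases, replace=False)] = 1
    return GenotypeMatrix(
        snp_ids=[f"rs{i}" for i in range(m)],
        genotypes=geno,
        phenotypes=pheno,
    )


@pytest.fixture
def random_gm():
    return make_random_gm


@pytest.fixture
def tiny_gm():
    """2 SNPs x 4 samples, the worked binarisation example."""
    return GenotypeMatrix(
        snp_ids=["rs0", "rs1"],
        genotypes=np.array([[0, 1, 2, 1], [2, 2, 0, 1]], dtype=np.int8),
        phenotypes=np.array([0, 0, 1, 1], dtype=np.int8),
    )
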