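import numpy as np
import pytest

from kccu import GenotypeMatrix, SnpRecord


def make_matrix(values, region="G", prefix="snp", sample_prefix="s"):
    """GenotypeMatrix from a plain array, with synthetic SNP metadata."""
    values = np.asarray(values, dtype=float)
    snps = []
    for j in range(values.shape[1]):
        col = values[:, j]
        ok = np.isfinite(col)
        maf = float(np.clip(col[ok].mean() / 2.0 if ok.any() else 0.25, 1e-6, 0.5))
        snps.append(SnpRecord(f"{prefix}{j + 1}", region, maf))
    ids = [f"{sample_prefix}{i + 1}" for i in range(values.shape[0])]
    return GenotypeMatrix(values, snps, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(2012)


@pytest.fixture
def random_pair(rng):
    """Two aligned dosage matrices, 200 individuals, 5 + 6 SNPs."""
    X = rng.integers(0, 3, (200, 5)).astype(float)
    Y = rng.integers(0, 3, (200, 6)).astype(float)
    return make_matrix(X, "A", "a"), make_matrix(Y, "B", "b")
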