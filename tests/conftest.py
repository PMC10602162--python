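import numpy as np
import pytest

from mdrscan import GenotypeMatrix, PhenotypeVector, VariantKey

BASES = "ACGT"


def make_matrix(codes, chrom="1", start=1000):
    """GenotypeMatrix from a nested list / array of codes (MISSING = -1)."""
    codes = np.asarray(codes, dtype=np.int8)
    variants = [
        VariantKey(chrom, start + 10 * v, "A", "G") for v in range(codes.shape[0])
    ]
    return GenotypeMatrix(variants=variants, codes=codes)


def random_dataset(rng, n_variants, n_individuals, missing_rate=0.05):
    """Random genotype matrix (with missing calls) and balanced-ish phenotype."""
    codes = rng.integers(0, 3, size=(n_variants, n_individuals)).astype(np.int8)
    miss = rng.random((n_variants, n_individuals)) < missing_rate
    codes[miss] = -1
    status = rng.integers(0, 2, size=n_individuals).astype(np.int8)
    # guarantee both classes
    status[0], status[1] = 1, 0
    return make_matrix(codes), PhenotypeVector(status=status)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
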