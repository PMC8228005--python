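import numpy as np
import pandas as pd
import pytest

from driftscan.genotypes import GenotypeMatrix


def make_geno(
    dosage,
    chroms=None,
    pos=None,
    groups=None,
    breeds=None,
    sample_ids=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array with default metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    samples = pd.DataFrame({
        "sample_id": sample_ids if sample_ids is not None else [f"s{i:03d}" for i in range(n)],
        "breed": breeds if breeds is not None else ["B"] * n,
        "group": groups if groups is not None else [None] * n,
    })
    variants = pd.DataFrame({
        "id": [f"v{j:04d}" for j in range(m)],
        "chrom": chroms if chroms is not None else ["1"] * m,
        "pos_bp": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "allele_a": ["A"] * m,
        "allele_b": ["C"] * m,
    })
    return GenotypeMatrix(dosage, samples, variants)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_group_geno(rng):
    """40+40 samples, 200 independent SNPs, no differentiation."""
    m, n = 200, 40
    p = rng.uniform(0.1, 0.5, m)
    d = rng.binomial(2, np.tile(p, (2 * n, 1))).astype(np.int8)
    return make_geno(d, groups=["I"] * n + ["II"] * n)
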