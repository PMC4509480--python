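import numpy as np
import pytest

from finestruct.genodata import MISSING, GenotypeDataset, VariantRecord


def random_dataset(
    rng: np.random.Generator,
    n_samples: int,
    n_snps: int,
    missing_rate: float = 0.0,
    maf_range=(0.1, 0.5),
) -> GenotypeDataset:
    """Random HWE dataset for oracle tests (binomial genotypes, no LD)."""
    p = rng.uniform(*maf_range, size=n_snps)
    g = rng.binomial(2, p, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    samples = [f"s{i:03d}" for i in range(n_samples)]
    variants = [
        VariantRecord(f"snp{j:04d}", "1", 1000 * (j + 1), "A", "C")
        for j in range(n_snps)
    ]
    return GenotypeDataset(samples, variants, g)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_ds(rng):
    return random_dataset(rng, 12, 30, missing_rate=0.05)
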