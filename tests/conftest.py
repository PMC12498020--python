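import numpy as np
import pytest

from cryptpc.genotype_io import MISSING, GenotypeMatrix, SampleRecord, SNPRecord


def random_matrix(
    rng: np.random.Generator,
    n_samples: int = 6,
    n_snps: int = 8,
    missing_rate: float = 0.15,
    populations: list[str] | None = None,
) -> GenotypeMatrix:
    """A small random genotype matrix with valid records."""
    calls = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    if populations is None:
        populations = [f"Pop{i % 2}" for i in range(n_samples)]
    samples = [
        SampleRecord(sample_id=f"S{i:02d}", population=populations[i],
                     sex="MFU"[i % 3])
        for i in range(n_samples)
    ]
    snps = [
        SNPRecord(snp_id=f"rs{j}", chromosome="1", genetic_pos=j * 1e-4,
                  physical_pos=100 * (j + 1), ref_allele="A", alt_allele="C")
        for j in range(n_snps)
    ]
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng)
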