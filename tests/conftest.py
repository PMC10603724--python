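import numpy as np
import pytest

from caprapop.genotypes import GenotypeMatrix, SNPRecord, SampleRecord


def make_gm(calls, positions=None, chroms=None, breeds=None, spacing=100_000,
            sample_ids=None):
    """Build a GenotypeMatrix from a raw (n_samples, n_snps) code array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [1 + j * spacing for j in range(m)]
    if chroms is None:
        chroms = ["1"] * m
    if breeds is None:
        breeds = ["X"] * n
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    snps = [
        SNPRecord(chrom=str(chroms[j]), id=f"snp{j:05d}", cm=0.0,
                  bp=int(positions[j]), ref="A", alt="C")
        for j in range(m)
    ]
    samples = [SampleRecord(sample_id=sample_ids[i], breed=breeds[i])
               for i in range(n)]
    return GenotypeMatrix(samples, snps, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    """Three lightly differentiated breeds, 20 samples each, 600 SNPs."""
    from caprapop.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_breeds=3, breed_sizes=(20, 20, 20), breed_names=("A", "B", "C"),
        n_snps=600, n_chroms=3, chrom_length=30_000_000,
        fst_per_breed=(0.1, 0.1, 0.1), missing_rate=0.02,
        n_related_pairs=2, seed=11,
    )
    return simulate_cohort(cfg)
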