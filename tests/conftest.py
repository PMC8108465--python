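import numpy as np
import pytest

from hybridforge.io import GenotypeMatrix, VariantInfo


def make_gm(dosages, positions=None, chrom="chr01", sample_ids=None):
    """Build a GenotypeMatrix from a samples x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(m)]
    if isinstance(chrom, str):
        chrom = [chrom] * m
    variants = [
        VariantInfo(f"{c}.s_{p}", c, int(p), "A", "T")
        for c, p in zip(chrom, positions)
    ]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants, dosages).with_maf()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_panel():
    """50 inbred lines x 200 independent variants."""
    from hybridforge.simulate import gen_inbred_genotypes

    return gen_inbred_genotypes(50, 200, seed=101, ld_block_len=1)
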