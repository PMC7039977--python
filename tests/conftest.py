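import numpy as np
import pandas as pd
import pytest

from paleostruct.fstats import GroupFrequencies
from paleostruct.io import DIPLOID, MISSING, PSEUDO_HAPLOID, GenotypeMatrix, make_blocks


def variant_frame(n_snps, chromosome="1", ancestral="A"):
    return pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n_snps)],
        "chromosome": chromosome,
        "position": np.arange(1, n_snps + 1, dtype=np.int64),
        "allele_ref": "A",
        "allele_alt": "G",
        "allele_ancestral": ancestral,
    })


def make_geno(calls, ploidy=None, groups=None, variants=None):
    """Build a GenotypeMatrix from a plain call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group_label": groups if groups is not None else "G",
        "ploidy_mode": ploidy if ploidy is not None else DIPLOID,
    })
    return GenotypeMatrix(calls, samples, variants if variants is not None
                          else variant_frame(m))


def random_group_counts(rng, n_groups, n_snps, max_n=10):
    """Random per-group allele counts with n >= 2 everywhere."""
    n = rng.integers(2, max_n + 1, size=(n_groups, n_snps)).astype(float)
    k = rng.binomial(n.astype(int), rng.uniform(0.05, 0.95, size=n.shape))
    return GroupFrequencies([f"G{i}" for i in range(n_groups)], k.astype(float), n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_blocks():
    """Blocks over a 10-SNP chromosome: sizes (5, 5)."""
    return make_blocks(variant_frame(10), blen=5)
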