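import numpy as np
import pandas as pd
import pytest

from haploscan.formats import HaplotypeMatrix, MarkerMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_map(n_snps, chrom="1", spacing=1000, start=1):
    pos = start + spacing * np.arange(n_snps)
    return MarkerMap(pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(n_snps)],
        "chrom": chrom,
        "pos": pos,
        "ref_allele": "A",
        "alt_allele": "G",
        "ancestral": "ref",
    }), validate=False)


def random_hap(rng, n_haps=20, n_snps=50):
    # reject fixed columns so every SNP is polymorphic
    values = rng.integers(0, 2, size=(n_haps, n_snps), dtype=np.int8)
    fixed = (values.mean(axis=0) == 0) | (values.mean(axis=0) == 1)
    values[0, fixed] = 1 - values[0, fixed]
    return HaplotypeMatrix(values)


@pytest.fixture
def small_hap_map(rng):
    hap = random_hap(rng, 20, 50)
    mmap = make_map(50)
    mmap.df["derived_freq"] = hap.derived_freq()
    mmap.df["maf"] = np.minimum(mmap.df["derived_freq"], 1 - mmap.df["derived_freq"])
    return hap, mmap
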