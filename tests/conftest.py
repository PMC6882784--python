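import numpy as np
import pandas as pd
import pytest

from clonevo.simulate import Genome, make_genes


@pytest.fixture(scope="session")
def small_genome():
    """Three short autosomes plus chrX — keeps full pipelines fast."""
    return Genome(
        chromosomes={"chr1": 8_000_000, "chr2": 8_000_000, "chr3": 8_000_000,
                     "chrX": 4_000_000}
    )


@pytest.fixture(scope="session")
def small_genes(small_genome):
    return make_genes(small_genome, n_per_chrom=20, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_chrom_genome():
    return Genome(chromosomes={"chr1": 25_000_000})


@pytest.fixture(scope="session")
def tiled_genes(single_chrom_genome):
    """200 evenly tiled genes on one chromosome for AI calibration tests."""
    idx = np.arange(200)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": idx * 120_000 + 10_000,
            "end": idx * 120_000 + 60_000,
            "gene": [f"G{i:03d}" for i in idx],
        }
    )
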