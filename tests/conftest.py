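import numpy as np
import pytest

from regulomics.intervals import GenomicInterval, Peak, Promoter
from regulomics.simulate import SyntheticSpec


@pytest.fixture
def toy_genome():
    return [("chr1", 10_000_000), ("chr2", 10_000_000)]


@pytest.fixture
def small_spec():
    """Desk-scale synthetic spec for fast recovery tests."""
    return SyntheticSpec(
        n_cell_lines=80,
        n_features=60,
        n_informative=5,
        n_genes=20,
        n_nonsignature_genes=10,
        n_background_links=15,
        n_rescue_genes=200,
        seed=11,
    )


@pytest.fixture
def promoter_chr1():
    return Promoter("GENE1", GenomicInterval("chr1", 100_000, 100_001, "+"))


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, 500))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + length))
    return out
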