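import numpy as np
import pandas as pd
import pytest

from sweepx.types import (
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationMap,
    SNPMap,
)


def make_snp_map(positions, chrom="X", ancestral=None):
    n = len(positions)
    anc = ancestral if ancestral is not None else ["ref"] * n
    return SNPMap(
        pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "chrom": chrom,
                "pos": positions,
                "ref": "A",
                "alt": "G",
                "ancestral": anc,
            }
        )
    )


@pytest.fixture
def tiny_map():
    return make_snp_map([100, 200, 300])


@pytest.fixture
def two_pop_panel():
    """4 + 4 samples, 5 SNPs, handmade phased haplotypes."""
    rng = np.random.default_rng(7)
    values = (rng.random((16, 5)) < 0.4).astype(np.int8)
    samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    H = HaplotypeMatrix(samples, values)
    pops = PopulationMap(
        {s: ("popA" if s.startswith("A") else "popB") for s in samples}
    )
    snp_map = make_snp_map([1000, 2000, 3500, 7000, 9000])
    return snp_map, H, pops


@pytest.fixture
def small_genotypes():
    values = np.array(
        [
            [0, 1, 2, 0],
            [0, 1, 2, 1],
            [1, 0, 2, 0],
            [2, 2, 2, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], values)
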