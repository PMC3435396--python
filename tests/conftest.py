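import numpy as np
import pytest

from kbas.genotypes import CohortPair, GenotypeMatrix
from kbas.simulate import SimulationSpec, simulate_null_pair, simulate_shifted_pair


@pytest.fixture
def tiny_matrix():
    """4 subjects x 3 SNPs with one missing call."""
    values = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, -1],
            [0, 2, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], ["rsA", "rsB", "rsC"], values)


@pytest.fixture
def small_null_pair():
    """Modest null cohort pair shared by statistical tests."""
    spec = SimulationSpec(n_case=150, n_control=150, n_snps=40, seed=11)
    return simulate_null_pair(spec)


@pytest.fixture
def small_shifted_pair():
    """Pair with three planted MAF-shift effects."""
    spec = SimulationSpec(
        n_case=300,
        n_control=300,
        n_snps=40,
        maf_range=(0.05, 0.3),
        causal_snps={0: 0.15, 1: 0.15, 2: 0.15},
        seed=7,
    )
    return simulate_shifted_pair(spec)
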