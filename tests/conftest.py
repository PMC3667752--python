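import numpy as np
import pytest

from heritkit.genotype_io import GenotypeMatrix
from heritkit.simulate import PairBlock, SimulationSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_genotypes(rng):
    """10 samples x 20 SNPs, no missing, polymorphic by construction."""
    counts = rng.integers(0, 3, size=(10, 20), dtype=np.int8)
    # force every SNP polymorphic with both alleles present
    counts[0] = 0
    counts[1] = 1
    counts[2] = 2
    return GenotypeMatrix([f"s{i}" for i in range(10)],
                          [f"m{j}" for j in range(20)], counts)


@pytest.fixture(scope="session")
def sib_cohort_small():
    """Scaled-down sib-pair cohort for unit-level estimator checks."""
    spec = SimulationSpec(pair_blocks=[PairBlock(100, 0.5)],
                          m_observed=500, m_unobserved=500, seed=7)
    return simulate_cohort(spec)
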