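import numpy as np
import pytest

from genomeforge.haplotype_io import HaplotypeMatrix
from genomeforge.synthetic_data import PopSimConfig, simulate_structured_haplotypes


@pytest.fixture(scope="session")
def structured_panel() -> HaplotypeMatrix:
    """A 3-population panel with realistic SFS and decaying LD."""
    return simulate_structured_haplotypes(
        PopSimConfig(n_pops=3, n_hap_per_pop=60, n_snps=300, fst=0.15, seed=11)
    )


@pytest.fixture(scope="session")
def two_cluster_panel() -> HaplotypeMatrix:
    """The scaled-down generative-recovery dataset: 2 clusters, 255 SNPs, 400 haplotypes."""
    return simulate_structured_haplotypes(
        PopSimConfig(n_pops=2, n_hap_per_pop=200, n_snps=255, fst=0.3, seed=1)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
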