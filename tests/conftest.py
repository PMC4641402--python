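import numpy as np
import pytest

from retroscan.syndata import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides) -> SimulationConfig:
    """A compact simulation: 2 scaffolds, 10 parents, 6 copies, 2 decoys."""
    defaults = dict(
        seed=7,
        n_scaffolds=2,
        scaffold_length=120_000,
        n_parent_genes=10,
        n_single_exon_genes=2,
        n_retrocopies=6,
        n_dna_duplication_decoys=2,
        cds_codon_range=(100, 200),
        masked_fraction=0.05,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())
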