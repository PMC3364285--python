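import numpy as np
import pytest

from intetax import SimConfig, evolve_sequences, simulate_species_tree


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic species complex shared by read-only tests."""
    cfg = SimConfig(seed=11)
    tree, part = simulate_species_tree(cfg)
    aln = evolve_sequences(tree, cfg, partition=part)
    return cfg, tree, part, aln


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
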