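import numpy as np
import pytest

from mitolineage.io_matrix import MutationId, from_counts


@pytest.fixture
def tiny_dataset():
    """2 mutations x 3 cells with one missing entry (depth 0)."""
    muts = [MutationId.parse("MT_100_A-G"), MutationId.parse("MT_16389_G-A")]
    cells = ["c1", "c2", "c3"]
    depth = np.array([[30, 30, 0], [10, 20, 30]])
    alt = np.array([[15, 0, 0], [1, 10, 30]])
    return from_counts(muts, cells, alt, depth, {"c1": "A", "c2": "A", "c3": "B"})


@pytest.fixture(scope="session")
def sim_default():
    """One seeded default simulation (100 cells, 6 clones, 30X)."""
    from mitolineage.simulate import SimConfig, simulate_dataset

    return simulate_dataset(SimConfig(seed=11))
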