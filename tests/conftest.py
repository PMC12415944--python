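import numpy as np
import pytest

from delimscale.simulate import SimConfig


def partition_sets(partition: dict[str, str]) -> frozenset:
    """Label-free view of a partition for equality checks."""
    return frozenset(
        frozenset(s for s, v in partition.items() if v == sp)
        for sp in set(partition.values())
    )


@pytest.fixture
def small_config():
    """A reduced paper-like configuration for fast pipeline tests.

    Five species, 16 samples, ~6 kb over 12 genes; same divergence scales
    as the full study conditions.
    """
    rng = np.random.default_rng(7)
    lengths = [int(x) for x in rng.integers(200, 900, size=12)]
    return SimConfig(
        n_species=5,
        samples_per_species=[5, 2, 3, 3, 3],
        birth_rate=1.0,
        root_height=0.04,
        theta=0.003,
        n_genes=12,
        gene_lengths=lengths,
        seed=11,
        min_split_frac=0.30,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
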