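import numpy as np
import pytest

from cocultureq.proteome_db import build_merged_database
from cocultureq.synthetic import (
    SyntheticConfig,
    simulate_proteomes,
    simulate_quant_table,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast dataset: 150 proteins per strain, 10 planted DE each."""
    return SyntheticConfig(
        n_proteins_a=150,
        n_proteins_b=150,
        protein_length_range=(100, 200),
        n_true_de=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_proteomes(small_cfg):
    return simulate_proteomes(small_cfg)


@pytest.fixture(scope="session")
def small_merged(small_proteomes):
    return build_merged_database(*small_proteomes)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_proteomes):
    """(table, design, truth) for the small config."""
    return simulate_quant_table(small_cfg, small_proteomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
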