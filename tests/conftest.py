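import pytest

from epinet.network_builder import EPINetwork
from epinet.synthetic_data import (
    SyntheticConfig,
    generate_epi_tables,
    generate_genome,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=11,
        n_enhancers_per_celltype=150,
        n_genes=100,
        n_tfs=30,
        n_case_variants=1500,
        n_control_variants=1500,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_epi_tables(small_config, generate_genome(small_config))


@pytest.fixture(scope="session")
def small_networks(small_dataset):
    return [EPINetwork(t, ct) for ct, t in small_dataset.epi_tables.items()]
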