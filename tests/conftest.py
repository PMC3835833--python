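import pytest

from twolib import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    """Toy study: 60 genes, modest libraries, reads emitted with planted
    contamination so every raw-read filter fires."""
    return SimulationConfig(
        n_genes=60,
        gene_length_range=(200, 800),
        library_sizes=(50_000, 50_000),
        de_fraction=0.2,
        fold_changes=(8.0, 0.125),
        n_terms=5,
        genes_per_term=10,
        seed=11,
        emit_reads=True,
        n_reads=400,
        adaptor_fraction=0.10,
        highn_fraction=0.05,
        lowq_fraction=0.05,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One seeded run at the default desk-scale study conditions."""
    return simulate_all(SimulationConfig(seed=5))
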