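import pytest

from epiregnet.simulate import SimulationConfig, simulate


def small_config(**overrides) -> SimulationConfig:
    """A reduced fixture: same planted structure, smaller genome."""
    params = dict(
        seed=1,
        n_chromosomes=4,
        chrom_length_bp=1_500_000,
        n_genes=300,
        n_tfs=30,
        n_master_tfs=5,
        n_noise_contacts=100,
        n_background_methylation_tiles=500,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def sim_default():
    """One full-scale simulated bundle shared by read-only tests."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture()
def sim_small():
    return simulate(small_config())
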