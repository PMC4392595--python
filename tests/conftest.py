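import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromdyn.genome import GeneModel, Genome
from chromdyn.simulate import (
    SimulationParams,
    make_gene_models,
    make_genome,
    plant_regulatory_landscape,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return make_genome(2, 1_000_000, seed=1)


@pytest.fixture(scope="session")
def toy_genes(small_genome) -> list[GeneModel]:
    return make_gene_models(small_genome, 60, 5000, seed=1)


@pytest.fixture(scope="session")
def toy_truth(small_genome, toy_genes):
    return plant_regulatory_landscape(
        small_genome,
        toy_genes,
        n_static=12,
        n_activated=12,
        n_esc_only=4,
        frac_brg1_bound=0.8,
        delta_bound=0.5,
        seed=1,
        n_polycomb=6,
        n_repressed_genes=10,
        n_nonpolycomb_up=4,
    )


@pytest.fixture(scope="session")
def sim_params() -> SimulationParams:
    return SimulationParams(read_depth=400_000, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
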