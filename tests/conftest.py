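import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from microkpnn_mt.knowledge import (
    MetabolicEdge,
    Role,
    build_hidden_schema,
    build_mask,
)


TOY_SPECIES = ["S1", "S2", "S3", "S4"]
TOY_EDGES = {
    MetabolicEdge("S1", "M1", Role.PRODUCER),
    MetabolicEdge("S2", "M1", Role.PRODUCER),
    MetabolicEdge("S3", "M1", Role.CONSUMER),
}
TOY_TAXMAP = {"S1": "G1", "S2": "G1", "S3": "G2", "S4": "G2"}
TOY_COMMMAP = {"S1": {"C1"}, "S3": {"C1"}}


@pytest.fixture
def toy_schema():
    """4-species toy: one metabolite, two genera, one community.

    Expected nodes (in order): M1_production{S1,S2}, M1_consumption{S3},
    genus_G1{S1,S2}, genus_G2{S3,S4}, community_C1{S1,S3},
    unknown_metabolite{S4}, unknown_community{S2,S4}.
    """
    return build_hidden_schema(TOY_SPECIES, TOY_EDGES, TOY_TAXMAP, TOY_COMMMAP)


@pytest.fixture
def toy_mask(toy_schema):
    return build_mask(toy_schema, TOY_SPECIES)


@pytest.fixture
def small_sim():
    """Small strong-signal cohort shared by training/attribution tests."""
    from microkpnn_mt.synthetic import SimSpec, simulate_dataset

    return simulate_dataset(SimSpec(n_samples=200, n_species=30, n_genera=10,
                                    n_metabolites=6, n_communities=4, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
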