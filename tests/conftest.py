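import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from impaesim.network_io import AssociationTable, NodeIndex, build_disease_network
from impaesim.synthetic import SyntheticConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_table() -> AssociationTable:
    """Three-edge disease-gene table with a hand-checkable adjacency."""
    return AssociationTable(
        "disease",
        "gene",
        {("d1", "g1"): 1.0, ("d1", "g2"): 2.0, ("d2", "g2"): 1.0},
    )


@pytest.fixture
def tiny_network(tiny_table):
    return build_disease_network(tiny_table, "disease_gene")


@pytest.fixture
def path_network():
    """Path graph d0 - g0 - d1 - g1 - d2 (5 nodes)."""
    table = AssociationTable(
        "disease",
        "gene",
        {("d0", "g0"): 1.0, ("d1", "g0"): 1.0, ("d1", "g1"): 1.0, ("d2", "g1"): 1.0},
    )
    return build_disease_network(table, "disease_gene")


@pytest.fixture
def small_synthetic():
    """Planted 3-community dataset small enough for exhaustive checks."""
    config = SyntheticConfig(
        n_diseases=30, n_genes=60, n_lncrnas=9, n_mirnas=18,
        n_communities=3, seed=7,
    )
    dg, gl, gm, labels = generate(config)
    return config, dg, gl, gm, labels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_index(*ids: str) -> NodeIndex:
    return NodeIndex.from_ids(ids, "disease")
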