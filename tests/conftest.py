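import numpy as np
import pytest

from mirnetdx.network import DiseaseNetwork, Interactome, build_disease_network


@pytest.fixture
def toy_interactome():
    """Three-edge toy: m1->{g1,g2}, m2->{g2}; g1 is a TF."""
    return Interactome(
        edges=(("m1", "g1"), ("m1", "g2"), ("m2", "g2")),
        tf_genes=frozenset({"g1"}),
        mirna_universe=frozenset({"m1", "m2"}),
    )


@pytest.fixture
def toy_network(toy_interactome):
    return build_disease_network(toy_interactome, {"g1", "g2"}, ["m1", "m2"])


def random_bipartite(rng, max_mirna=8, max_gene=20):
    """Random bipartite edge set + TF/DE subsets; guaranteed non-empty."""
    while True:
        n_m = rng.integers(2, max_mirna + 1)
        n_g = rng.integers(2, max_gene + 1)
        mirnas = [f"m{i}" for i in range(n_m)]
        genes = [f"g{i}" for i in range(n_g)]
        prob = rng.uniform(0.1, 0.6)
        edges = [
            (m, g) for m in mirnas for g in genes if rng.random() < prob
        ]
        de = {g for g in genes if rng.random() < 0.7}
        tf = {g for g in genes if rng.random() < 0.3}
        if any(g in de for _, g in edges):
            return mirnas, genes, edges, de, tf
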