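import numpy as np
import pytest

from lncgat.data_io import AssociationMatrix, DiseaseGeneMap, GeneInteractionNetwork
from lncgat.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_assoc():
    """3 lncRNAs x 2 diseases with profiles (1,0), (0,1), (1,1)."""
    return AssociationMatrix(
        ["l1", "l2", "l3"], ["d1", "d2"], np.array([[1, 0], [0, 1], [1, 1]])
    )


@pytest.fixture
def path_net():
    """Path graph g1 - g2 - g3 - g4."""
    return GeneInteractionNetwork(
        ["g1", "g2", "g3", "g4"],
        {frozenset(("g1", "g2")), frozenset(("g2", "g3")), frozenset(("g3", "g4"))},
    )


def random_association(rng, L=10, D=8, p=0.3):
    values = (rng.random((L, D)) < p).astype(int)
    if values.sum() == 0:
        values[0, 0] = 1
    return AssociationMatrix(
        [f"l{i}" for i in range(L)], [f"d{j}" for j in range(D)], values
    )


def random_network(rng, n=20, p=0.15):
    genes = [f"g{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add(frozenset((genes[i], genes[j])))
    return GeneInteractionNetwork(genes, edges)


def random_attributed_graph(rng, n_nodes, n_features, y=0, p_edge=0.4):
    """A random attributed graph wrapped as a scoreable subgraph."""
    from lncgat.features import AttributedSubgraph
    from lncgat.subgraph import EnclosingSubgraph

    nodes = [("l" if i % 2 == 0 else "d", i, 1, 0) for i in range(n_nodes)]
    edges = [
        (u, v)
        for u in range(n_nodes)
        for v in range(u + 1, n_nodes)
        if rng.random() < p_edge
    ]
    sub = EnclosingSubgraph((0, 1), 1, nodes, edges, (0, 1), y)
    return AttributedSubgraph(sub, rng.normal(size=(n_nodes, n_features)))


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-structure dataset for fast pipeline tests."""
    return generate(
        SyntheticSpec(L=16, D=12, lncrna_blocks=2, disease_blocks=2, n_genes=60,
                      genes_per_disease=6, seed=42)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default 40 x 30 planted-structure dataset."""
    return generate(SyntheticSpec(seed=1))
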