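import networkx as nx
import numpy as np
import pytest

from bstk.copsets import SpeciesTree
from bstk.ontology import AnnotationSet, OntologyGraph


@pytest.fixture
def chain_graph():
    """root <- mid <- leaf is_a chain in one namespace."""
    g = nx.DiGraph()
    for t in ("GO:0000001", "GO:0000002", "GO:0000003"):
        g.add_node(t, name=t, namespace="biological_process")
    g.add_edge("GO:0000003", "GO:0000002", relation="is_a")
    g.add_edge("GO:0000002", "GO:0000001", relation="is_a")
    return OntologyGraph(g)


@pytest.fixture
def diamond_graph():
    """Two paths of different length from a leaf to the root.

    root <- a <- b <- leaf (length 3) and root <- c <- leaf (length 2).
    """
    g = nx.DiGraph()
    for t in ("root", "a", "b", "c", "leaf"):
        g.add_node(t, name=t, namespace="bp")
    g.add_edge("a", "root", relation="is_a")
    g.add_edge("b", "a", relation="is_a")
    g.add_edge("c", "root", relation="is_a")
    g.add_edge("leaf", "b", relation="is_a")
    g.add_edge("leaf", "c", relation="is_a")
    return OntologyGraph(g)


@pytest.fixture
def two_namespace_graph():
    g = nx.DiGraph()
    for t, ns in [
        ("bp_root", "bp"),
        ("bp_mid", "bp"),
        ("mf_root", "mf"),
        ("mf_mid", "mf"),
    ]:
        g.add_node(t, name=t, namespace=ns)
    g.add_edge("bp_mid", "bp_root", relation="is_a")
    g.add_edge("mf_mid", "mf_root", relation="is_a")
    return OntologyGraph(g)


@pytest.fixture
def species_tree():
    return SpeciesTree()


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Random single-namespace DAG: each non-root picks parents among
    earlier terms, so term 0 is the unique root."""
    g = nx.DiGraph()
    names = [f"T{i:02d}" for i in range(n_terms)]
    for t in names:
        g.add_node(t, name=t, namespace="ns")
    for i in range(1, n_terms):
        n_parents = 1 + rng.integers(0, min(i, 3))
        for j in rng.choice(i, size=n_parents, replace=False):
            g.add_edge(names[i], names[int(j)], relation="is_a")
    return OntologyGraph(g)
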