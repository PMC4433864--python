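"""Shared fixtures: tiny hand-traceable networks and random-instance helpers."""

from itertools import combinations

import networkx as nx
import pytest


@pytest.fixture
def two_clique_bridge():
    """K5 {A1..A5} and K4 {B1..B4} joined by the single bridge A1–B1,
    each clique carrying one private annotation term on every member."""
    graph = nx.Graph()
    a = [f"A{i}" for i in range(1, 6)]
    b = [f"B{i}" for i in range(1, 5)]
    graph.add_edges_from(combinations(a, 2))
    graph.add_edges_from(combinations(b, 2))
    graph.add_edge("A1", "B1")
    annotations = {node: {"term_a"} for node in a}
    annotations.update({node: {"term_b"} for node in b})
    return graph, annotations, [frozenset(a), frozenset(b)]


def random_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi graph over string node names (deterministic in seed)."""
    graph = nx.gnp_random_graph(n_nodes, p, seed=seed)
    return nx.relabel_nodes(graph, {i: f"P{i:02d}" for i in graph.nodes()})


@pytest.fixture
def k3_expression():
    """3 genes × 2 collapsed time points, values chosen hand-checkable."""
    import pandas as pd

    return pd.DataFrame(
        [[1.0, 3.0], [5.0, 5.0], [4.0, 0.0]],
        index=pd.Index(["A", "B", "C"], name="gene"),
        columns=["t1", "t2"],
    )
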