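"""Combined PPI networks: the dynamic network weighted by shared GO-slim terms.

Each GO-slim term defines a *GO-Protein-Set*, the network proteins carrying
that annotation.  Every unordered pair of proteins sharing at least one term
gets an edge whose integer weight is the number of shared terms; dynamic PPI
edges are always kept (weight possibly 0).  Edge origins:

* ``ppi`` — a dynamic PPI edge whose endpoints share no term (weight 0);
* ``both`` — a dynamic PPI edge whose endpoints share >=1 term;
* ``go_added`` — a pair sharing terms with no dynamic PPI edge.

GO never adds nodes: the combined node set equals the dynamic node set.
All three annotation aspects (BP/MF/CC) contribute indiscriminately.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import networkx as nx

__all__ = ["build_go_protein_sets", "build_combined"]


def build_go_protein_sets(
    annotations: dict[str, set[str]], network: nx.Graph
) -> dict[str, set[str]]:
    """Invert a protein→terms map to term→proteins, restricted to network nodes.

    Terms left with fewer than two member proteins are retained (they simply
    generate no edges downstream).
    """
    nodes = set(network.nodes())
    sets: dict[str, set[str]] = {}
    for protein, terms in annotations.items():
        if protein not in nodes:
            continue
        for term in terms:
            sets.setdefault(term, set()).add(protein)
    # keep annotated-but-absent terms visible as empty sets
    for terms in annotations.values():
        for term in terms:
            sets.setdefault(term, set())
    return sets


def build_combined(network: nx.Graph, go_protein_sets: dict[str, set[str]]) -> nx.Graph:
    """Weight a dynamic network by shared-term counts and add annotation edges.

    The weight of pair (u, v) equals |terms(u) ∩ terms(v)|, accumulated by
    counting each term's member pairs once (a pair sharing k terms yields a
    single edge of weight k, never parallel edges).  The number of edges
    created purely by annotation is stored in
    ``graph.graph["added_edge_count"]``.
    """
    weights: Counter = Counter()
    for members in go_protein_sets.values():
        for u, v in combinations(sorted(members), 2):
            weights[(u, v) if u < v else (v, u)] += 1

    combined = nx.Graph()
    combined.add_nodes_from(network.nodes())
    added = 0
    for (u, v), weight in weights.items():
        if network.has_edge(u, v):
            combined.add_edge(u, v, weight=weight, origin="both")
        else:
            combined.add_edge(u, v, weight=weight, origin="go_added")
            added += 1
    for u, v in network.edges():
        if not combined.has_edge(u, v):
            combined.add_edge(u, v, weight=0, origin="ppi")
    combined.graph["added_edge_count"] = added
    return combined
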