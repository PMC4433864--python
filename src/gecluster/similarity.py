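"""FS-Weight functional similarity and the cluster density statistic.

FS-Weight scores two proteins by how much their interaction neighborhoods
overlap, with a pseudo-count penalty for low-degree proteins.  Using closed
neighborhoods N_i (the neighbors of i *including i itself*):

    FS(i, j) =   2|N_i ∩ N_j| / (|N_i − N_j| + 2|N_i ∩ N_j| + λ_ij)
               · 2|N_i ∩ N_j| / (|N_j − N_i| + 2|N_i ∩ N_j| + λ_ji)

    λ_ij = max(0, N_avg − (|N_i − N_j| + |N_i ∩ N_j|)) = max(0, N_avg − |N_i|)

where N_avg = 2|E|/|V| is the average degree of the network the context was
built from (the dynamic PPI network).  FS is symmetric and lies in [0, 1];
λ discounts proteins whose degree falls below the network average, so that
two sparsely characterised proteins are not declared similar on thin
evidence.  Two proteins are called *strongly similar* when FS meets a
threshold (inclusive).

The cluster density statistic of a candidate complex with n nodes and m
internal edges is

    Cluster_Coefficient = 2m / (n(n − 1))

i.e. the fraction of possible internal edges that are present; it is 1
exactly for cliques and strictly decreases when an unconnected node joins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx

__all__ = [
    "DENSITY_TOL",
    "FSWeightContext",
    "fs_weight",
    "is_strong",
    "ClusterDensity",
    "cluster_coefficient",
]

#: A density "decrease" means new < old − DENSITY_TOL.
DENSITY_TOL = 1e-12


class FSWeightContext:
    """Closed neighborhoods and average degree of a network, for FS-Weight.

    Built once per network; pairs need not be adjacent (the score of a
    candidate against an arbitrary current cluster member is a legal query).
    """

    __slots__ = ("closed", "n_avg")

    def __init__(self, network: nx.Graph):
        self.closed: dict[Hashable, frozenset] = {
            node: frozenset(network[node]) | {node} for node in network.nodes()
        }
        n = network.number_of_nodes()
        self.n_avg: float = (2.0 * network.number_of_edges() / n) if n else 0.0

    def __contains__(self, node) -> bool:
        return node in self.closed


def fs_weight(ctx: FSWeightContext, i, j) -> float:
    """FS-Weight similarity between two distinct proteins of the context."""
    if i == j:
        raise ValueError("fs_weight requires two distinct proteins")
    try:
        n_i, n_j = ctx.closed[i], ctx.closed[j]
    except KeyError as missing:
        raise KeyError(f"protein {missing.args[0]!r} not in FS-Weight context") from None
    common = len(n_i & n_j)
    if common == 0:
        return 0.0
    only_i = len(n_i) - common
    only_j = len(n_j) - common
    lam_ij = max(0.0, ctx.n_avg - len(n_i))
    lam_ji = max(0.0, ctx.n_avg - len(n_j))
    return (2.0 * common / (only_i + 2.0 * common + lam_ij)) * (
        2.0 * common / (only_j + 2.0 * common + lam_ji)
    )


def is_strong(similarity: float, fs_min: float) -> bool:
    """True when a similarity reaches the strong-similarity threshold (inclusive)."""
    if not 0.0 <= fs_min <= 1.0:
        raise ValueError("fs_min must lie in [0, 1]")
    return similarity >= fs_min


@dataclass(frozen=True)
class ClusterDensity:
    """Internal edge count m, node count n and the density 2m/(n(n−1))."""

    m: int
    n: int
    value: float


def cluster_coefficient(cluster: Iterable, graph: nx.Graph) -> ClusterDensity:
    """Density of a candidate cluster over a graph's edges (any weight).

    ``m`` counts graph edges with both endpoints in the cluster; clusters of
    fewer than two nodes are rejected.
    """
    members = set(cluster)
    n = len(members)
    if n < 2:
        raise ValueError("cluster density requires at least 2 nodes")
    # each internal edge seen from both endpoints
    twice_m = sum(
        1 for u in members if u in graph for v in graph[u] if v in members
    )
    m = twice_m // 2
    return ClusterDensity(m=m, n=n, value=2.0 * m / (n * (n - 1)))
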