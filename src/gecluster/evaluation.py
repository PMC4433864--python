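"""Complex-level evaluation: overlap matching, Recall/Precision/F1, network stats.

A predicted complex A and a reference complex B are compared with the
neighborhood-affinity matching score

    M_Score(A, B) = |V_A ∩ V_B|² / (|V_A| · |V_B|)

which is symmetric, 0 iff the complexes are disjoint and 1 iff they are
identical.  A pair with M_Score >= M_thres (default 0.2) is a match.  With
N_c reference and N_p predicted complexes, N_mc references matched by >=1
prediction and N_mp predictions matched by >=1 reference:

    Recall = N_mc / N_c      Precision = N_mp / N_p
    F1 = 2 · Recall · Precision / (Recall + Precision)

Network statistics reported alongside: average local clustering
coefficient (nodes of degree < 2 contribute 0), network diameter (maximum
shortest-path length over connected pairs), characteristic path length
(mean shortest-path length over connected pairs), and the degree and
shortest-path-length histograms.  Disconnected networks are handled per
component; a component count is reported.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "m_score",
    "MatchResult",
    "match_sets",
    "recall",
    "precision",
    "f1",
    "evaluate",
    "NetworkStats",
    "network_stats",
    "curate_reference",
]


def m_score(a, b) -> float:
    """Matching score |A∩B|²/(|A|·|B|) between two non-empty protein sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("m_score requires two non-empty complexes")
    shared = len(a & b)
    return shared * shared / (len(a) * len(b))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a predicted complex set against a reference set."""

    n_c: int
    n_p: int
    n_mc: int
    n_mp: int
    m_thres: float
    pairs: list = field(default_factory=list)  # (ref index, pred index, score)


def match_sets(reference, predicted, m_thres: float = 0.2) -> MatchResult:
    """Match every reference/predicted pair at a threshold.

    A pair matches iff ``m_score >= m_thres``; ``n_mc``/``n_mp`` count
    distinct matched complexes, not pairs.
    """
    if not 0.0 < m_thres <= 1.0:
        raise ValueError("m_thres must lie in (0, 1]")
    matched_ref: set[int] = set()
    matched_pred: set[int] = set()
    pairs = []
    for i, ref in enumerate(reference):
        for j, pred in enumerate(predicted):
            score = m_score(ref, pred)
            if score >= m_thres:
                matched_ref.add(i)
                matched_pred.add(j)
                pairs.append((i, j, score))
    return MatchResult(
        n_c=len(reference),
        n_p=len(predicted),
        n_mc=len(matched_ref),
        n_mp=len(matched_pred),
        m_thres=m_thres,
        pairs=pairs,
    )


def _safe_ratio(numerator: int, denominator: int, name: str) -> float:
    if denominator == 0:
        warnings.warn(f"{name}: empty denominator, reporting 0", stacklevel=3)
        return 0.0
    return numerator / denominator


def recall(result: MatchResult) -> float:
    """Fraction of reference complexes matched by at least one prediction."""
    return _safe_ratio(result.n_mc, result.n_c, "recall")


def precision(result: MatchResult) -> float:
    """Fraction of predicted complexes matched by at least one reference."""
    return _safe_ratio(result.n_mp, result.n_p, "precision")


def f1(r: float, p: float) -> float:
    """Harmonic mean of recall and precision (0 when both vanish)."""
    if r + p == 0:
        return 0.0
    return 2.0 * r * p / (r + p)


def evaluate(reference, predicted, m_thres: float = 0.2) -> dict:
    """Convenience: match and report all complex-level metrics as a dict."""
    result = match_sets(reference, predicted, m_thres)
    r, p = recall(result), precision(result)
    return {
        "n_c": result.n_c,
        "n_p": result.n_p,
        "n_mc": result.n_mc,
        "n_mp": result.n_mp,
        "m_thres": m_thres,
        "recall": r,
        "precision": p,
        "f1": f1(r, p),
    }


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_components: int
    clustering_coefficient: float
    diameter: int
    characteristic_path_length: float
    degree_histogram: dict
    path_length_histogram: dict


def network_stats(network: nx.Graph) -> NetworkStats:
    """Topological summary of a (possibly disconnected) network.

    Path statistics run over connected node pairs only; the diameter is the
    maximum over components.  Histogram invariants: the degree histogram
    sums to the node count, the path-length histogram to the number of
    connected unordered pairs.
    """
    n = network.number_of_nodes()
    clustering = nx.average_clustering(network) if n else 0.0
    degree_hist = Counter(d for _, d in network.degree())
    path_hist: Counter = Counter()
    total = 0
    count = 0
    diameter = 0
    for source, lengths in nx.all_pairs_shortest_path_length(network):
        for target, distance in lengths.items():
            if distance == 0:
                continue
            path_hist[distance] += 1  # each unordered pair counted twice
            total += distance
            count += 1
    path_hist = Counter({d: c // 2 for d, c in path_hist.items()})
    if count:
        diameter = max(path_hist)
    return NetworkStats(
        n_nodes=n,
        n_edges=network.number_of_edges(),
        n_components=nx.number_connected_components(network) if n else 0,
        clustering_coefficient=clustering,
        diameter=diameter,
        characteristic_path_length=(total / count) if count else 0.0,
        degree_histogram=dict(sorted(degree_hist.items())),
        path_length_histogram=dict(sorted(path_hist.items())),
    )


def curate_reference(complexes, nodes, min_size: int = 3):
    """Restrict reference complexes to proteins present in an evaluated network.

    Each complex is intersected with ``nodes`` and dropped when fewer than
    ``min_size`` members survive — the usual curation when benchmarking
    against a condition-specific network whose genes are only partly
    expressed.  Never increases the reference count.
    """
    nodes = set(nodes)
    curated = []
    for cluster in complexes:
        surviving = frozenset(cluster) & nodes
        if len(surviving) >= min_size:
            curated.append(frozenset(surviving))
    return curated
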