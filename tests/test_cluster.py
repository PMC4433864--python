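"""Seed-expansion clusterer: hand-traced recoveries, admission rules, determinism."""

import networkx as nx
import pytest

from gecluster import GECluster, build_combined, build_go_protein_sets, run
from gecluster.cluster import density_audit
from gecluster import io

from conftest import random_graph


def combined_from(graph, annotations):
    return build_combined(graph, build_go_protein_sets(annotations, graph))


class TestHandTracedInstances:
    def test_two_planted_cliques_with_bridge_recovered_exactly(self, two_clique_bridge):
        graph, annotations, truth = two_clique_bridge
        found = run(combined_from(graph, annotations), graph, fs_min=0.25)
        assert sorted(map(sorted, found)) == sorted(map(sorted, truth))

    def test_single_triangle_with_uniform_annotations(self):
        graph = nx.complete_graph(["A", "B", "C"])
        annotations = {n: {"t"} for n in graph}
        found = run(combined_from(graph, annotations), graph, min_size=3)
        assert found == [frozenset({"A", "B", "C"})]

    def test_edgeless_network_yields_no_clusters(self):
        graph = nx.Graph()
        graph.add_nodes_from("ABC")
        assert run(combined_from(graph, {}), graph) == []

    def test_empty_network_is_not_an_error(self):
        assert run(nx.Graph()) == []

    def test_isolated_seed_discarded_by_min_size(self):
        graph = nx.Graph([("A", "B"), ("A", "C"), ("B", "C")])
        graph.add_node("Z")
        found = run(combined_from(graph, {n: {"t"} for n in "ABC"}), graph)
        assert found == [frozenset("ABC")]


class TestAdmissionRules:
    def test_fs_failure_rejects_even_when_density_would_not_drop(self):
        # Z completes a clique with the triangle (density stays 1) but is a
        # hub of pendant leaves, so its neighborhood barely overlaps the
        # triangle's and FS-Weight falls below a high threshold.
        graph = nx.complete_graph(["A", "B", "C"])
        for node in "ABC":
            graph.add_edge(node, "Z")
        for leaf in range(12):
            graph.add_edge("Z", f"L{leaf}")
        annotations = {n: {"t"} for n in "ABCZ"}
        model = GECluster(fs_min=0.9, min_size=3).fit(combined_from(graph, annotations), graph)
        assert frozenset("ABC") in model.complexes_
        assert all("Z" not in c for c in model.complexes_)
        assert model.stats_["rejected_fs"] > 0

    def test_density_drop_rejects_even_strong_candidates(self, two_clique_bridge):
        # With fs_min=0 every pair is "strongly similar"; only the density
        # rule separates the cliques, and the bridge node is still refused.
        graph, annotations, truth = two_clique_bridge
        model = GECluster(fs_min=0.0).fit(combined_from(graph, annotations), graph)
        assert sorted(map(sorted, model.complexes_)) == sorted(map(sorted, truth))
        assert model.stats_["rejected_density"] > 0

    def test_fs_min_one_emits_only_identically_neighborhooded_cliques(self):
        graph = nx.disjoint_union_all(
            [nx.complete_graph(4), nx.complete_graph(3), nx.path_graph(4)]
        )
        found = run(build_combined(graph, {}), graph, fs_min=1.0)
        for cluster in found:
            sub = graph.subgraph(cluster)
            assert sub.number_of_edges() == len(cluster) * (len(cluster) - 1) // 2

    def test_disjoint_assignment_by_default(self, two_clique_bridge):
        graph, annotations, _ = two_clique_bridge
        model = GECluster().fit(combined_from(graph, annotations), graph)
        seen = set()
        for cluster in model.complexes_:
            assert not cluster & seen
            seen |= cluster

    def test_overlap_mode_can_reuse_assigned_members(self):
        # Two triangles sharing node S; with overlap, S joins both.
        graph = nx.Graph(
            [("A", "B"), ("A", "S"), ("B", "S"), ("C", "D"), ("C", "S"), ("D", "S")]
        )
        annotations = {n: {"t1"} for n in "ABS"} | {n: {"t2"} for n in "CDS"}
        annotations["S"] = {"t1", "t2"}
        found = run(combined_from(graph, annotations), graph, fs_min=0.0, overlap=True)
        assert sum("S" in c for c in found) == 2

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="share a node set"):
            GECluster().fit(nx.complete_graph(3), nx.complete_graph(4))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GECluster(fs_min=2.0).fit(nx.Graph())
        with pytest.raises(ValueError):
            GECluster(min_size=1).fit(nx.Graph())


class TestEstimatorContract:
    def test_get_set_params_round_trip(self):
        model = GECluster(fs_min=0.5, min_size=4)
        params = model.get_params()
        assert params["fs_min"] == 0.5
        clone = GECluster().set_params(**params)
        assert clone.get_params() == params

    def test_fitted_attributes(self, two_clique_bridge):
        graph, annotations, _ = two_clique_bridge
        model = GECluster().fit(combined_from(graph, annotations), graph)
        assert model.n_seeds_ >= 2
        assert model.labels_["A1"] != model.labels_["B1"]
        assert set(model.stats_) == {
            "accepted", "rejected_fs", "rejected_density", "discarded_small",
        }


@pytest.mark.parametrize("seed", range(8))
def test_structural_invariants_on_random_instances(seed):
    """Emitted clusters are connected, >= min_size, disjoint and audit-clean."""
    import random

    graph = random_graph(18, 0.25, seed)
    rng = random.Random(seed)
    annotations = {
        node: {f"t{rng.randint(0, 4)}"} for node in graph.nodes() if rng.random() < 0.8
    }
    combined = combined_from(graph, annotations)
    found = run(combined, graph, fs_min=0.2)
    seen = set()
    for cluster in found:
        assert len(cluster) >= 3
        assert nx.is_connected(combined.subgraph(cluster))
        assert not cluster & seen
        seen |= cluster
    assert density_audit(found, combined)


def test_byte_identical_output_across_reruns(tmp_path, two_clique_bridge):
    graph, annotations, _ = two_clique_bridge
    paths = []
    for name in ("first", "second"):
        found = run(combined_from(graph, annotations), graph)
        path = tmp_path / f"{name}.tsv"
        io.write_complexes(found, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()
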