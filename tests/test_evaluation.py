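"""Complex matching, Recall/Precision/F1 and network statistics."""

import random

import networkx as nx
import pytest

from gecluster import (
    curate_reference,
    f1,
    m_score,
    match_sets,
    network_stats,
    precision,
    recall,
)


def oracle_match(reference, predicted, m_thres):
    """Brute-force double loop with an independently written score."""
    def score(a, b):
        inter = sum(1 for x in a if x in b)
        return (inter / len(a)) * (inter / len(b))

    matched_ref = {i for i, r in enumerate(reference) if any(score(r, p) >= m_thres for p in predicted)}
    matched_pred = {j for j, p in enumerate(predicted) if any(score(r, p) >= m_thres for r in reference)}
    return len(matched_ref), len(matched_pred)


class TestMScore:
    def test_identity_and_disjoint(self):
        assert m_score({"A", "B"}, {"A", "B"}) == 1.0
        assert m_score({"A"}, {"B"}) == 0.0

    def test_hand_evaluated_overlap(self):
        # |A|=4, |B|=5, shared 2: 2² / (4·5) = 0.2
        a = {"P1", "P2", "P3", "P4"}
        b = {"P3", "P4", "P5", "P6", "P7"}
        assert m_score(a, b) == pytest.approx(0.2, abs=1e-15)

    def test_symmetry_and_range_on_random_sets(self):
        rng = random.Random(0)
        universe = [f"P{i}" for i in range(20)]
        for _ in range(50):
            a = set(rng.sample(universe, rng.randint(1, 10)))
            b = set(rng.sample(universe, rng.randint(1, 10)))
            assert m_score(a, b) == pytest.approx(m_score(b, a), abs=1e-15)
            assert 0.0 <= m_score(a, b) <= 1.0

    def test_empty_complex_rejected(self):
        with pytest.raises(ValueError):
            m_score(set(), {"A"})


class TestMatchSets:
    def test_identical_sets_fully_matched(self):
        sets = [frozenset("AB"), frozenset("CD"), frozenset("EF")]
        result = match_sets(sets, list(sets))
        assert (result.n_mc, result.n_mp) == (3, 3)

    def test_empty_predictions(self):
        result = match_sets([frozenset("AB")], [])
        assert (result.n_mc, result.n_mp) == (0, 0)

    def test_counts_distinct_complexes_not_pairs(self):
        reference = [frozenset("ABC")]
        predicted = [frozenset("ABX"), frozenset("BCY")]
        result = match_sets(reference, predicted, m_thres=0.4)
        assert result.n_mc == 1 and result.n_mp == 2
        assert len(result.pairs) == 2

    @pytest.mark.parametrize("seed", range(100))
    def test_brute_force_agreement_on_random_instances(self, seed):
        rng = random.Random(seed)
        universe = [f"P{i}" for i in range(30)]
        reference = [
            frozenset(rng.sample(universe, rng.randint(2, 8))) for _ in range(5)
        ]
        predicted = [
            frozenset(rng.sample(universe, rng.randint(2, 8))) for _ in range(7)
        ]
        m_thres = rng.choice([0.1, 0.2, 0.5, 1.0])
        result = match_sets(reference, predicted, m_thres)
        assert (result.n_mc, result.n_mp) == oracle_match(reference, predicted, m_thres)

    def test_threshold_bounds_rejected(self):
        with pytest.raises(ValueError):
            match_sets([], [], m_thres=0.0)


class TestScores:
    def test_perfect_prediction(self):
        result = match_sets([frozenset("AB")], [frozenset("AB")])
        r, p = recall(result), precision(result)
        assert (r, p, f1(r, p)) == (1.0, 1.0, 1.0)

    def test_zero_recall_gives_zero_f1(self):
        assert f1(0.0, 0.7) == 0.0

    def test_f1_equals_rate_when_balanced(self):
        assert f1(0.6, 0.6) == pytest.approx(0.6, abs=1e-15)

    def test_empty_denominators_warn_and_report_zero(self):
        result = match_sets([], [])
        with pytest.warns(UserWarning):
            assert recall(result) == 0.0
        with pytest.warns(UserWarning):
            assert precision(result) == 0.0


class TestNetworkStats:
    def test_triangle(self):
        stats = network_stats(nx.complete_graph(3))
        assert stats.clustering_coefficient == pytest.approx(1.0)
        assert stats.diameter == 1
        assert stats.characteristic_path_length == pytest.approx(1.0)

    def test_path_of_three(self):
        stats = network_stats(nx.path_graph(3))
        assert stats.clustering_coefficient == 0.0
        assert stats.diameter == 2
        assert stats.characteristic_path_length == pytest.approx(4 / 3)

    def test_star(self):
        stats = network_stats(nx.star_graph(3))
        assert stats.diameter == 2

    def test_histograms_conserve_counts(self):
        graph = nx.gnp_random_graph(15, 0.2, seed=3)
        stats = network_stats(graph)
        assert sum(stats.degree_histogram.values()) == stats.n_nodes
        connected_pairs = sum(
            n * (n - 1) // 2
            for n in (len(c) for c in nx.connected_components(graph))
        )
        assert sum(stats.path_length_histogram.values()) == connected_pairs

    def test_disconnected_network_reports_components(self):
        graph = nx.disjoint_union(nx.path_graph(3), nx.path_graph(2))
        stats = network_stats(graph)
        assert stats.n_components == 2
        assert stats.diameter == 2  # max over components


class TestCuration:
    def test_restrict_and_drop(self):
        reference = [frozenset("ABCD"), frozenset("XYZ")]
        curated = curate_reference(reference, nodes={"A", "B", "C", "X"}, min_size=3)
        assert curated == [frozenset("ABC")]

    def test_never_increases_reference_count(self):
        rng = random.Random(1)
        universe = [f"P{i}" for i in range(20)]
        reference = [frozenset(rng.sample(universe, 5)) for _ in range(10)]
        nodes = set(rng.sample(universe, 12))
        assert len(curate_reference(reference, nodes)) <= len(reference)
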