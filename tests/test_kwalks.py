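"""Bounded K-walk passage counts and relevant-subnetwork extraction."""

import networkx as nx
import pytest

from oracles import monte_carlo_passages

from drugspn import kwalks, rwr
from drugspn.kwalks import AbsorbingChainSpec


class TestBoundedExpectedPassages:
    def test_forced_single_step(self):
        g = nx.Graph([("A", "B")])
        T = rwr.transition_matrix(g)
        for l_max in (1, 5, 50):
            table = kwalks.bounded_expected_passages(
                AbsorbingChainSpec(T, "A", frozenset({"B"}), l_max)
            )
            assert table.passages[("A", "B")] == pytest.approx(1.0)

    def test_unreachable_component_gets_zero(self):
        g = nx.Graph([("A", "B"), ("X", "Y")])
        T = rwr.transition_matrix(g)
        table = kwalks.bounded_expected_passages(AbsorbingChainSpec(T, "A", frozenset({"B"}), 10))
        assert ("X", "Y") not in table.passages

    @pytest.mark.parametrize(
        "edges,start,absorbing,l_max",
        [
            ([("A", "B"), ("B", "C")], "A", {"C"}, 10),
            ([("A", "B"), ("B", "C"), ("C", "D")], "A", {"D"}, 12),
            ([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")], "A", {"D"}, 15),
        ],
    )
    def test_matches_monte_carlo_oracle(self, edges, start, absorbing, l_max):
        g = nx.Graph(edges)
        T = rwr.transition_matrix(g)
        exact = kwalks.bounded_expected_passages(
            AbsorbingChainSpec(T, start, frozenset(absorbing), l_max)
        )
        mc = monte_carlo_passages(T, start, absorbing, l_max, n_walks=100_000, seed=42)
        for (u, v), value in exact.passages.items():
            est, se = mc.get((u, v), (0.0, 0.0))
            assert abs(value - est) <= max(3 * se, 1e-3), (u, v, value, est)

    def test_total_absorption_approaches_one(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("B", "D")])
        T = rwr.transition_matrix(g)
        table = kwalks.bounded_expected_passages(AbsorbingChainSpec(T, "A", frozenset({"D"}), 400))
        absorbed = sum(v for (u, w), v in table.passages.items() if w == "D")
        assert absorbed == pytest.approx(1.0, abs=1e-6)

    def test_empty_absorbing_rejected(self, path3):
        T = rwr.transition_matrix(path3)
        with pytest.raises(ValueError, match="absorbing"):
            AbsorbingChainSpec(T, "A", frozenset(), 5)

    def test_start_in_absorbing_rejected(self, path3):
        T = rwr.transition_matrix(path3)
        with pytest.raises(ValueError, match="absorbing"):
            AbsorbingChainSpec(T, "A", frozenset({"A", "C"}), 5)

    def test_flow_consistency_on_toy(self):
        # for a transient non-start node: inflow - outflow = mass stranded
        # there at the step bound (>= 0)
        g = nx.Graph([("A", "B"), ("B", "C")])
        T = rwr.transition_matrix(g)
        table = kwalks.bounded_expected_passages(AbsorbingChainSpec(T, "A", frozenset({"C"}), 7))
        inflow = sum(v for (u, w), v in table.passages.items() if w == "B")
        outflow = sum(v for (u, w), v in table.passages.items() if u == "B")
        assert inflow - outflow >= -1e-12


class TestAggregateRelevance:
    def test_two_seeds_single_edge_gives_unit_relevance(self):
        g = nx.Graph([("A", "B")])
        T = rwr.transition_matrix(g)
        rel = kwalks.aggregate_relevance(g, {"A", "B"}, T, l_max=10)
        assert rel.undirected()[("A", "B")] == pytest.approx(1.0)

    def test_symmetric_in_seed_ordering(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("B", "D")])
        T = rwr.transition_matrix(g)
        r1 = kwalks.aggregate_relevance(g, ["A", "C", "D"], T, l_max=20)
        r2 = kwalks.aggregate_relevance(g, ["D", "A", "C"], T, l_max=20)
        assert r1.passages == r2.passages

    def test_mean_of_per_start_tables(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("A", "E"), ("E", "C"), ("B", "D")])
        T = rwr.transition_matrix(g)
        seeds = ["A", "C", "D"]
        agg = kwalks.aggregate_relevance(g, seeds, T, l_max=15)
        manual = {}
        for start in seeds:
            t = kwalks.bounded_expected_passages(
                AbsorbingChainSpec(T, start, frozenset(s for s in seeds if s != start), 15)
            )
            for e, v in t.passages.items():
                manual[e] = manual.get(e, 0.0) + v / len(seeds)
        assert set(agg.passages) == set(manual)
        for e in manual:
            assert agg.passages[e] == pytest.approx(manual[e], rel=1e-12)

    def test_single_mapped_seed_rejected(self, path3):
        T = rwr.transition_matrix(path3)
        with pytest.raises(ValueError, match=">= 2"):
            kwalks.aggregate_relevance(path3, {"A", "ZZ"}, T)


class TestExtractSubnetwork:
    def test_equal_relevance_returns_full_seed_component(self, triangle):
        T = rwr.transition_matrix(triangle)
        rel = kwalks.EdgeRelevanceTable(
            list(triangle.nodes),
            {(u, v): 0.5 for u, v in triangle.edges} | {(v, u): 0.5 for u, v in triangle.edges},
            {},
        )
        sub = kwalks.extract_subnetwork(triangle, rel, {"A", "C"})
        assert set(sub.nodes) == {"A", "B", "C"}
        assert sub.number_of_edges() == 3

    def test_low_relevance_pendant_dropped(self):
        # chain s1-a-s2 plus pendant a-x with lower relevance
        g = nx.Graph([("s1", "a"), ("a", "s2"), ("a", "x")])
        passages = {
            ("s1", "a"): 0.9, ("a", "s1"): 0.0,
            ("a", "s2"): 0.9, ("s2", "a"): 0.0,
            ("a", "x"): 0.1, ("x", "a"): 0.0,
        }
        rel = kwalks.EdgeRelevanceTable(list(g.nodes), passages, {})
        sub = kwalks.extract_subnetwork(g, rel, {"s1", "s2"})
        assert set(sub.nodes) == {"s1", "a", "s2"}
        assert not sub.has_edge("a", "x")

    def test_disconnected_seeds_returned_as_singletons(self, caplog):
        g = nx.Graph([("A", "B"), ("X", "Y")])
        passages = {("A", "B"): 0.5, ("X", "Y"): 0.5}
        rel = kwalks.EdgeRelevanceTable(list(g.nodes), passages, {})
        with caplog.at_level("WARNING"):
            sub = kwalks.extract_subnetwork(g, rel, {"A", "X", "Q"})
        assert "A" in sub.nodes and "X" in sub.nodes

    def test_adding_edge_never_disconnects_seed_pairs(self):
        g = nx.Graph([("s1", "a"), ("a", "s2")])
        passages = {("s1", "a"): 0.8, ("a", "s2"): 0.8}
        rel = kwalks.EdgeRelevanceTable(list(g.nodes), dict(passages), {})
        base = kwalks.extract_subnetwork(g, rel, {"s1", "s2"})
        g2 = g.copy()
        g2.add_edge("s1", "s2")
        rel2 = kwalks.EdgeRelevanceTable(list(g2.nodes), {**passages, ("s1", "s2"): 0.9}, {})
        richer = kwalks.extract_subnetwork(g2, rel2, {"s1", "s2"})
        assert nx.has_path(base, "s1", "s2")
        assert nx.has_path(richer, "s1", "s2")
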