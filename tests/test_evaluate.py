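"""GWAS gene-level aggregation, enrichment statistics and topology metrics."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_force_cpm, enumeration_tail_table

from drugspn import evaluate


def snp_df(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])


def gene_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


class TestGeneMinP:
    GENES = gene_df([("chr1", 100_000, 110_000, "G1"), ("chr1", 400_000, 410_000, "G2"), ("chr2", 100_000, 110_000, "G3")])

    def test_gene_without_snp_is_missing(self):
        snps = snp_df([("rs1", "chr1", 105_000, 0.5)])
        out = evaluate.gene_min_p(snps, self.GENES, window=20_000).set_index("gene")
        assert np.isnan(out.loc["G2", "min_p"])
        assert not out.loc["G2", "related"]

    def test_window_lower_bound_closed_upper_open(self):
        snps = snp_df(
            [
                ("rs_lo", "chr1", 100_000 - 20_000, 0.01),  # exactly start - W: in
                ("rs_hi", "chr1", 410_000 + 20_000, 0.01),  # exactly end + W: out
            ]
        )
        out = evaluate.gene_min_p(snps, self.GENES, window=20_000).set_index("gene")
        assert out.loc["G1", "min_p"] == 0.01
        assert np.isnan(out.loc["G2", "min_p"])

    def test_toy_enumeration_of_minima(self):
        snps = snp_df(
            [
                ("rs1", "chr1", 105_000, 0.5),
                ("rs2", "chr1", 95_000, 0.2),
                ("rs3", "chr1", 405_000, 0.8),
                ("rs4", "chr2", 90_001, 0.001),
                ("rs5", "chr2", 200_000, 0.3),
                ("rs6", "chr1", 300_000, 0.0001),
            ]
        )
        out = evaluate.gene_min_p(snps, self.GENES, window=20_000).set_index("gene")
        assert out.loc["G1", "min_p"] == 0.2  # rs1, rs2 in window; rs6 not
        assert out.loc["G2", "min_p"] == 0.8
        assert out.loc["G3", "min_p"] == 0.001
        assert out.loc["G3", "related"] and not out.loc["G2", "related"]

    def test_invariant_to_snp_row_order(self):
        snps = snp_df(
            [("rs1", "chr1", 105_000, 0.5), ("rs2", "chr1", 101_000, 0.2), ("rs3", "chr2", 105_000, 0.9)]
        )
        a = evaluate.gene_min_p(snps, self.GENES)
        b = evaluate.gene_min_p(snps.iloc[::-1].reset_index(drop=True), self.GENES)
        pd.testing.assert_frame_equal(a, b)

    def test_out_of_range_p_rejected(self):
        snps = snp_df([("rs1", "chr1", 105_000, 1.5)])
        with pytest.raises(ValueError, match="outside"):
            evaluate.gene_min_p(snps, self.GENES)


def enumeration_tail(N, K, n, k):
    """P(X >= k) by enumerating all C(N, n) draws (exact rational)."""
    return enumeration_tail_table(N, K, n)[k]


class TestHypergeomTest:
    def test_k_zero_gives_one(self):
        assert evaluate.hypergeom_test(100, 10, 20, 0) == 1.0

    def test_small_toy_matches_full_enumeration(self):
        expected = enumeration_tail(10, 4, 5, 3)
        assert evaluate.hypergeom_test(10, 4, 5, 3) == pytest.approx(float(expected), rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate.hypergeom_test(10, 12, 5, 3)
        with pytest.raises(ValueError):
            evaluate.hypergeom_test(10, 4, 5, 6)

    def test_deep_tail_matches_exact_rational_sum(self):
        # far below where naive cdf-complement arithmetic loses the tail
        from math import comb

        N, K, n, k = 2000, 100, 100, 60
        exact = Fraction(
            sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)), comb(N, n)
        )
        p = evaluate.hypergeom_test(N, K, n, k)
        assert p == pytest.approx(float(exact), rel=1e-10)
        assert p < 1e-50

    def test_enrichment_wrapper_restricts_to_population(self):
        res = evaluate.enrichment({"a", "b", "zz"}, {"b", "c", "qq"}, {"a", "b", "c", "d"})
        assert (res.N, res.K, res.n, res.k) == (4, 2, 2, 1)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert evaluate.bh_adjust([0.04]) == [pytest.approx(0.04)]

    def test_hand_stepup_example(self):
        assert evaluate.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_identical_ps_stay_equal(self):
        out = evaluate.bh_adjust([0.2, 0.2, 0.2])
        assert out == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evaluate.bh_adjust([0.5, 0.0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_bounded(self, ps):
        adj = evaluate.bh_adjust(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(a <= 1.0 + 1e-15 for a in adj)
        # monotone in the sorted-p order
        order = np.argsort(ps)
        sorted_adj = np.array(adj)[order]
        assert np.all(np.diff(sorted_adj) >= -1e-12)


class TestCategoryZscores:
    def test_arithmetic_oracle(self):
        # counts [4, 2, 0]: u = 2, population sigma = sqrt(8/3)
        out = evaluate.category_zscores({"a": 4, "b": 2, "c": 0}).set_index("category")
        sigma = np.sqrt(8 / 3)
        assert out.loc["a", "z"] == pytest.approx((4 - 2) / sigma)
        assert out.loc["b", "z"] == pytest.approx(0.0)
        assert out.loc["c", "z"] == pytest.approx(-(4 - 2) / sigma)
        assert list(out["selected"]) == [True, False, False]

    def test_mean_of_zscores_is_zero(self):
        out = evaluate.category_zscores({"a": 7, "b": 1, "c": 4, "d": 0})
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_equal_counts_error_path(self):
        with pytest.raises(ValueError, match="sigma"):
            evaluate.category_zscores({"a": 3, "b": 3})

    def test_invariant_to_category_order(self):
        a = evaluate.category_zscores({"x": 1, "y": 5, "z": 3})
        b = evaluate.category_zscores({"z": 3, "x": 1, "y": 5})
        pd.testing.assert_frame_equal(a, b)


class TestDegreeStats:
    def test_triangle(self, triangle):
        deg, mean, hist = evaluate.degree_stats(triangle)
        assert (deg == 2).all() and mean == 2.0
        assert hist.to_dict() == {2: 3}

    def test_star(self, star5):
        deg, mean, _ = evaluate.degree_stats(star5)
        assert sorted(deg) == [1, 1, 1, 1, 4]
        assert mean == pytest.approx(1.6)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            evaluate.degree_stats(nx.Graph())


class TestHubNodes:
    def test_strict_inequality(self, star5):
        assert evaluate.hub_nodes(star5, cutoff=1) == {"X"}
        assert evaluate.hub_nodes(star5, cutoff=4) == set()

    def test_quantile_strategy(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("c", "e")])
        # degrees: a=1, b=2, c=3, d=1, e=1 -> CDF reaches 0.5 at degree 1
        hubs = evaluate.hub_nodes(g, quantile=0.5)
        assert hubs == {"b", "c"}

    def test_exactly_one_strategy_required(self, star5):
        with pytest.raises(ValueError):
            evaluate.hub_nodes(star5)
        with pytest.raises(ValueError):
            evaluate.hub_nodes(star5, cutoff=2, quantile=0.5)


class TestKCliqueCommunities:
    def test_single_triangle(self, triangle):
        assert evaluate.kclique_communities(triangle) == [{"A", "B", "C"}]

    def test_two_triangles_sharing_one_node_stay_separate(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("D", "E"), ("C", "E")])
        comms = evaluate.kclique_communities(g, k=3)
        assert sorted(map(sorted, comms)) == [["A", "B", "C"], ["C", "D", "E"]]

    def test_single_edge_has_no_community(self):
        assert evaluate.kclique_communities(nx.Graph([("A", "B")])) == []

    def test_k_below_three_rejected(self, triangle):
        with pytest.raises(ValueError):
            evaluate.kclique_communities(triangle, k=2)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, 0.45, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        assert evaluate.kclique_communities(g, 3) == brute_force_cpm(g, 3)


class TestTableIO:
    def test_snp_and_gene_model_loaders(self, tmp_path):
        snp_path = tmp_path / "snps.tsv"
        snp_path.write_text("rs1\tchr1\t100\t0.5\nrs2\tchr2\t200\t0.01\n")
        gm_path = tmp_path / "genes.tsv"
        gm_path.write_text("chr1\t50\t150\tG1\n")
        snps = evaluate.load_snp_table(snp_path)
        genes = evaluate.load_gene_models(gm_path)
        assert len(snps) == 2 and len(genes) == 1
        out = evaluate.gene_min_p(snps, genes, window=0)
        assert out.loc[0, "min_p"] == 0.5

    def test_bad_gene_model_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("chr1\t150\t100\tG1\n")
        with pytest.raises(ValueError, match="start"):
            evaluate.load_gene_models(p)
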