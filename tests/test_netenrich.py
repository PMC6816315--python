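"""PPI clustering, permutation enrichment, set overlap, phenotype overlap."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from phenopleio.netenrich import (
    GeneSetLibrary,
    overlap_enrichment,
    phenotype_overlap,
    ppi_components,
    ppi_enrichment_p,
)

from .oracles import graph_components, overlap_tail_p


def _graph(edges):
    g = nx.Graph()
    for a, b, s in edges:
        g.add_edge(a, b, combined_score=s)
    return g


class TestPpiComponents:
    def test_cutoff_splits_chain(self):
        g = _graph([("A", "B", 0.9), ("B", "C", 0.5), ("C", "D", 0.3)])
        clusters, singles = ppi_components({"A", "B", "C", "D"}, g)
        assert clusters == [["A", "B", "C"]]
        assert singles == ["D"]  # 0.3 fails the strict > 0.4 rule

    def test_no_edges_above_cutoff(self):
        g = _graph([("A", "B", 0.2), ("B", "C", 0.1)])
        clusters, singles = ppi_components({"A", "B", "C"}, g)
        assert clusters == [] and singles == ["A", "B", "C"]

    def test_complete_triangle(self):
        g = _graph([("A", "B", 0.95), ("B", "C", 0.95), ("A", "C", 0.95)])
        clusters, singles = ppi_components({"A", "B", "C"}, g)
        assert clusters == [["A", "B", "C"]] and singles == []

    def test_missing_genes_become_singletons(self, caplog):
        g = _graph([("A", "B", 0.9)])
        with caplog.at_level("WARNING"):
            clusters, singles = ppi_components({"A", "B", "Z"}, g)
        assert clusters == [["A", "B"]] and singles == ["Z"]
        assert any("absent" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_partition_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(12)]
        edges = []
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < 0.2:
                    s = float(rng.random())
                    g.add_edge(nodes[i], nodes[j], combined_score=s)
                    if s > 0.4:
                        edges.append((nodes[i], nodes[j]))
        clusters, singles = ppi_components(set(nodes), g)
        expected = graph_components(nodes, edges)
        got = [set(c) for c in clusters] + [{s} for s in singles]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))
        # partition property
        assert sorted(sum(map(list, got), [])) == sorted(nodes)


class TestPpiEnrichment:
    def _background(self, seed=5, n=100, p=0.05):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        nodes = [f"n{i}" for i in range(n)]
        g.add_nodes_from(nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(nodes[i], nodes[j],
                               combined_score=float(rng.random()))
        return g, nodes

    def test_planted_clique_is_detected(self):
        g, nodes = self._background()
        clique = nodes[:5]
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(clique[i], clique[j], combined_score=0.95)
        p = ppi_enrichment_p(clique, g, n_perm=999, seed=1)
        assert p <= 0.01

    def test_edgeless_graph_p_one(self):
        g = nx.Graph()
        g.add_nodes_from("abcdefgh")
        assert ppi_enrichment_p(set("abcd"), g, n_perm=199, seed=0) == 1.0

    def test_whole_node_set_p_one(self):
        g = _graph([("A", "B", 0.9), ("B", "C", 0.8), ("C", "A", 0.7)])
        assert ppi_enrichment_p({"A", "B", "C"}, g, n_perm=199, seed=0) == 1.0

    def test_unique_planting_attains_minimum(self):
        # clique plus isolated nodes: no other 5-subset ties the edge count
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(60))
        clique = [f"n{i}" for i in range(5)]
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(clique[i], clique[j], combined_score=0.9)
        p = ppi_enrichment_p(clique, g, n_perm=199, seed=3)
        assert p == pytest.approx(1 / 200)

    def test_fixed_seed_is_bit_reproducible(self):
        g, nodes = self._background()
        p1 = ppi_enrichment_p(nodes[:8], g, n_perm=299, seed=11)
        p2 = ppi_enrichment_p(nodes[:8], g, n_perm=299, seed=11)
        assert p1 == p2

    def test_small_set_warns_and_returns_one(self, caplog):
        g = _graph([("A", "B", 0.9)])
        with caplog.at_level("WARNING"):
            assert ppi_enrichment_p({"A"}, g, n_perm=199, seed=0) == 1.0


class TestOverlapEnrichment:
    def test_exact_tail_example(self):
        lib = GeneSetLibrary({"s": frozenset(f"g{i}" for i in range(5))})
        background = [f"g{i}" for i in range(20)]
        query = {"g0", "g1", "g2", "g10", "g11"}
        (res,) = overlap_enrichment(query, lib, background)
        assert (res.k, res.K, res.n_query, res.N) == (3, 5, 5, 20)
        assert res.p == pytest.approx(1126 / 15504, rel=1e-12)

    def test_zero_overlap_p_one(self):
        lib = GeneSetLibrary({"s": frozenset({"a", "b"})})
        (res,) = overlap_enrichment({"x", "y"}, lib, {"a", "b", "x", "y"})
        assert res.p == 1.0

    def test_empty_query_rejected(self):
        lib = GeneSetLibrary({"s": frozenset({"a"})})
        with pytest.raises(ValueError):
            overlap_enrichment(set(), lib)

    def test_matches_enumeration_small_universe(self):
        # all query draws from N <= 12 enumerated exactly
        for N, K, n in [(8, 3, 4), (10, 5, 5), (12, 6, 4), (12, 4, 6)]:
            bg = [f"g{i}" for i in range(N)]
            lib = GeneSetLibrary({"s": frozenset(bg[:K])})
            for k in range(0, min(K, n) + 1):
                query = set(bg[:k]) | set(bg[K:K + (n - k)])
                (res,) = overlap_enrichment(query, lib, bg)
                assert res.k == k
                expected = float(overlap_tail_p(N, K, n, k))
                assert res.p == pytest.approx(expected, rel=1e-12)

    def test_q_monotone_with_p_and_flags(self):
        sets = {f"s{i}": frozenset({f"g{i}", f"g{i + 1}"}) for i in range(6)}
        lib = GeneSetLibrary(sets)
        res = overlap_enrichment({"g0", "g1"}, lib)
        ordered = sorted(res, key=lambda r: r.p)
        assert all(a.q <= b.q + 1e-12 for a, b in zip(ordered, ordered[1:]))
        assert all(r.q >= r.p - 1e-12 for r in res)


class TestPhenotypeOverlap:
    def test_planted_term_trait_pair(self):
        rows = phenotype_overlap(
            {"CARD14": {"HP:0003765"}},
            {"CARD14": {"Psoriasis"}},
            [("HP:0003765", "Psoriasis")],
        )
        assert len(rows) == 1
        assert rows.iloc[0].tolist() == ["CARD14", "HP:0003765", "Psoriasis"]

    def test_term_without_trait_yields_nothing(self):
        rows = phenotype_overlap(
            {"g": {"HP:1"}}, {"g": {"other"}}, [("HP:1", "trait")]
        )
        assert len(rows) == 0

    def test_empty_crosswalk_empty_output(self):
        rows = phenotype_overlap({"g": {"HP:1"}}, {"g": {"t"}}, [])
        assert len(rows) == 0

    def test_monotone_in_crosswalk(self):
        gene_terms = {"g1": {"HP:1", "HP:2"}, "g2": {"HP:2"}}
        gene_traits = {"g1": {"t1"}, "g2": {"t2"}}
        small = phenotype_overlap(gene_terms, gene_traits, [("HP:1", "t1")])
        big = phenotype_overlap(
            gene_terms, gene_traits, [("HP:1", "t1"), ("HP:2", "t2")]
        )
        small_rows = set(map(tuple, small.values))
        big_rows = set(map(tuple, big.values))
        assert small_rows <= big_rows
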