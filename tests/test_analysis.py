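"""Comparative network statistics on small planted graphs."""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from ddnplus import analysis, network


def build_graph(direct=(), indirect=(), nodes=(), categories=None):
    direct_map = {network.pair_key(a, b): ["rs1"] for a, b in direct}
    indirect_map = {}
    for a, b, *traits in indirect:
        indirect_map[network.pair_key(a, b)] = sorted(traits) or ["T"]
    attrs = {n: {"category": c} for n, c in (categories or {}).items()}
    return network.merge(direct_map, indirect_map, nodes=list(nodes),
                         node_attrs=attrs)


class TestDegreeRanks:
    def test_identical_graphs_have_zero_rank_change(self):
        g = build_graph(direct=[("a", "b"), ("b", "c")], nodes="abcd")
        table = analysis.degree_rank_change(g, g)
        assert (table["rank_change"] == 0).all()
        assert not table["newly_connected"].any()

    def test_isolated_node_gaining_edges_is_flagged_newly_connected(self):
        ssddn = build_graph(direct=[("a", "b")], nodes="abcdef")
        plus = build_graph(direct=[("a", "b")],
                           indirect=[("f", x) for x in "abcde"], nodes="abcdef")
        table = analysis.degree_rank_change(ssddn, plus)
        assert bool(table.loc["f", "newly_connected"])
        assert table.loc["f", "degree_ssddnplus"] == 5
        assert table.loc["f", "rank_ssddnplus"] == 1

    def test_hand_computed_competition_ranking_with_ties(self):
        # planted degrees ssddn: a=3, b=2, c=2, d=1, e=0  -> ranks 1,2,2,4,5
        ssddn = build_graph(direct=[("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")],
                            nodes="abcde")
        table = analysis.degree_rank_change(ssddn, ssddn)
        assert table["rank_ssddn"].to_dict() == {
            "a": 1, "b": 2, "c": 2, "d": 4, "e": 5}

    def test_mismatched_node_sets_error(self):
        with pytest.raises(ValueError, match="node sets"):
            analysis.degree_rank_change(build_graph(nodes="ab"),
                                        build_graph(nodes="abc"))


class TestCategoryPairs:
    def test_single_within_category_edge_stays_on_diagonal(self):
        g = build_graph(direct=[("a", "b")], nodes="ab",
                        categories={"a": "x", "b": "x"})
        cpm = analysis.category_pair_counts(g)
        assert cpm.raw.loc["x", "x"] == 1
        off = cpm.raw.to_numpy() - np.diag(np.diag(cpm.raw.to_numpy()))
        assert off.sum() == 0

    def test_normalization_by_category_sizes(self):
        cats = {c: "A" for c in "abc"} | {c: "B" for c in "defg"}
        g = build_graph(direct=[("a", "d")], nodes="abcdefg", categories=cats)
        cpm = analysis.category_pair_counts(g)
        assert cpm.normalized.loc["A", "B"] == pytest.approx(1 / 12)
        assert cpm.node_counts.to_dict() == {"A": 3, "B": 4}

    def test_planted_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(21)
        nodes = [f"n{i}" for i in range(16)]
        cats = {n: f"c{rng.integers(4)}" for n in nodes}
        pairs = list(combinations(nodes, 2))
        rng.shuffle(pairs)
        direct = pairs[:20]
        g = build_graph(direct=direct, nodes=nodes, categories=cats)
        cpm = analysis.category_pair_counts(g, edge_class="direct")
        for ca in cpm.categories:
            for cb in cpm.categories:
                expected = sum(1 for a, b in direct
                               if {cats[a], cats[b]} == ({ca, cb} if ca != cb
                                                         else {ca}))
                assert cpm.raw.loc[ca, cb] == expected
        assert cpm.total_edges() == 20  # conservation

    def test_missing_category_is_hard_error(self):
        g = build_graph(direct=[("a", "b")], nodes="ab", categories={"a": "x"})
        with pytest.raises(ValueError, match="category"):
            analysis.category_pair_counts(g)


class TestCrossCategoryFraction:
    def test_all_within_category_gives_zero(self):
        g = build_graph(direct=[("a", "b"), ("b", "c")], nodes="abc",
                        categories={n: "x" for n in "abc"})
        assert analysis.cross_category_fraction(g) == 0.0

    def test_star_with_distinct_leaf_categories_gives_one(self):
        g = build_graph(direct=[("h", x) for x in "abc"], nodes="habc",
                        categories={"h": "X", "a": "A", "b": "B", "c": "C"})
        assert analysis.cross_category_fraction(g) == 1.0

    def test_planted_sixty_of_eighty_cross_edges(self):
        nodes = [f"n{i}" for i in range(100)]
        cats = {n: ("L" if i < 50 else "R") for i, n in enumerate(nodes)}
        cross = [(nodes[i], nodes[50 + i]) for i in range(50)] \
            + [(nodes[i], nodes[51 + i]) for i in range(10)]
        within = [(nodes[i], nodes[i + 1]) for i in range(20)]
        g = build_graph(direct=cross + within, nodes=nodes, categories=cats)
        assert g.number_of_edges() == 80
        assert analysis.cross_category_fraction(g) == pytest.approx(60 / 80)

    def test_edgeless_graph_is_undefined(self):
        g = build_graph(nodes="ab", categories={"a": "x", "b": "y"})
        assert math.isnan(analysis.cross_category_fraction(g))

    def test_invariant_under_category_relabeling(self):
        nodes = "abcdef"
        cats = {"a": "x", "b": "y", "c": "x", "d": "z", "e": "y", "f": "z"}
        edges = [("a", "b"), ("c", "d"), ("e", "f"), ("a", "c")]
        g1 = build_graph(direct=edges, nodes=nodes, categories=cats)
        relabel = {"x": "q1", "y": "q2", "z": "q3"}
        g2 = build_graph(direct=edges, nodes=nodes,
                         categories={n: relabel[c] for n, c in cats.items()})
        assert (analysis.cross_category_fraction(g1)
                == analysis.cross_category_fraction(g2))


class TestConnectedNodeCount:
    def test_counts(self):
        assert analysis.connected_node_count(build_graph(nodes="abc")) == 0
        assert analysis.connected_node_count(
            build_graph(direct=[("a", "b")], nodes="abc")) == 2

    def test_planted_isolated_nodes(self):
        # 20 nodes, a path over the first 13 -> 7 isolated, 13 connected
        nodes = [f"n{i}" for i in range(20)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(12)]
        g = build_graph(direct=edges, nodes=nodes)
        assert analysis.connected_node_count(g) == 13
        assert analysis.connected_node_count(g) == sum(
            1 for n in g if g.degree(n) > 0)


class TestBiomarkerContribution:
    def test_trait_linking_only_direct_pairs_is_all_redundant(self):
        ssddn = build_graph(direct=[("a", "b")], nodes="abc")
        plus = build_graph(direct=[("a", "b")],
                           indirect=[("a", "b", "HDL")], nodes="abc")
        table = analysis.biomarker_contribution(ssddn, plus)
        assert table.loc["HDL", "new_edges"] == 0
        assert table.loc["HDL", "redundant_edges"] == 1

    def test_trait_with_no_associations_reports_zero_zero(self):
        ssddn = build_graph(nodes="ab")
        plus = build_graph(nodes="ab")
        table = analysis.biomarker_contribution(ssddn, plus, traits=["ALB"])
        assert table.loc["ALB"].to_dict() == {
            "new_edges": 0, "redundant_edges": 0, "total_memberships": 0}

    def test_overlapping_cliques_match_brute_force_attribution(self):
        # HDL clique {a,b,c}; TG clique {b,c,d}; direct edges (a,b), (c,d)
        direct = [("a", "b"), ("c", "d")]
        indirect = [("a", "b", "HDL"), ("a", "c", "HDL"), ("b", "c", "HDL", "TG"),
                    ("b", "d", "TG"), ("c", "d", "TG")]
        ssddn = build_graph(direct=direct, nodes="abcd")
        plus = build_graph(direct=direct, indirect=indirect, nodes="abcd")
        table = analysis.biomarker_contribution(ssddn, plus)
        # brute force: HDL links ab(direct), ac(new), bc(new) ; TG: bc(new),
        # bd(new), cd(direct)
        assert table.loc["HDL"].to_dict() == {
            "new_edges": 2, "redundant_edges": 1, "total_memberships": 3}
        assert table.loc["TG"].to_dict() == {
            "new_edges": 2, "redundant_edges": 1, "total_memberships": 3}

    def test_conservation_of_memberships(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(12)]
        pairs = list(combinations(nodes, 2))
        direct = [p for p in pairs if rng.uniform() < 0.15]
        indirect = []
        for a, b in pairs:
            traits = [t for t in ("HDL", "TG", "CRP") if rng.uniform() < 0.1]
            if traits:
                indirect.append((a, b, *traits))
        ssddn = build_graph(direct=direct, nodes=nodes)
        plus = build_graph(direct=direct, indirect=indirect, nodes=nodes)
        table = analysis.biomarker_contribution(ssddn, plus)
        for trait in table.index:
            total = sum(1 for e in indirect if trait in e[2:])
            assert table.loc[trait, "total_memberships"] == total


class TestSubnetwork:
    def _graph(self):
        return build_graph(direct=[("a", "b"), ("c", "d")],
                           indirect=[("a", "c", "HDL")], nodes="abcde")

    def test_full_subset_reproduces_graph(self):
        g = self._graph()
        sub = analysis.extract_subnetwork(g, list(g.nodes))
        assert network.graph_signature(sub) == network.graph_signature(g)

    def test_subset_without_internal_edges_is_edgeless(self):
        sub = analysis.extract_subnetwork(self._graph(), ["b", "d", "e"])
        assert sub.number_of_edges() == 0 and set(sub.nodes) == {"b", "d", "e"}

    def test_matches_brute_force_edge_filter_and_is_idempotent(self):
        g = self._graph()
        subset = ["a", "b", "c"]
        sub = analysis.extract_subnetwork(g, subset)
        expected = {network.pair_key(u, v) for u, v in g.edges()
                    if u in subset and v in subset}
        assert {network.pair_key(u, v) for u, v in sub.edges()} == expected
        again = analysis.extract_subnetwork(sub, subset)
        assert network.graph_signature(again) == network.graph_signature(sub)

    def test_unknown_node_is_hard_error(self):
        with pytest.raises(ValueError, match="unknown"):
            analysis.extract_subnetwork(self._graph(), ["a", "nope"])


class TestAdjacencyReport:
    def test_no_indirect_edges_means_no_focal_cells(self):
        g = build_graph(direct=[("a", "b")], nodes="abc")
        rep = analysis.adjacency_matrix_report(g, ["a", "b", "c"], "HDL")
        assert (rep.matrix.to_numpy() == analysis.ADJ_FOCAL).sum() == 0
        assert rep.matrix.loc["a", "b"] == analysis.ADJ_DIRECT

    def test_lower_triangle_counts_linking_traits(self):
        g = build_graph(indirect=[("a", "b", "HDL", "TG", "CRP")], nodes="ab")
        rep = analysis.adjacency_matrix_report(g, ["a", "b"], "HDL")
        assert rep.matrix.loc["b", "a"] == 3
        assert rep.matrix.loc["a", "b"] == analysis.ADJ_FOCAL

    def test_planted_fixture_matches_brute_force(self):
        nodes = list("abcd")
        direct = [("a", "b")]
        indirect = [("a", "b", "HDL"), ("a", "c", "HDL"), ("b", "d", "TG")]
        g = build_graph(direct=direct, indirect=indirect, nodes=nodes)
        rep = analysis.adjacency_matrix_report(g, nodes, "HDL")
        mat = rep.matrix
        # brute force expectations
        assert mat.loc["a", "b"] == analysis.ADJ_DIRECT      # direct wins
        assert mat.loc["a", "c"] == analysis.ADJ_FOCAL
        assert mat.loc["b", "d"] == analysis.ADJ_NONE        # TG, not focal
        assert mat.loc["b", "a"] == 1 and mat.loc["c", "a"] == 1
        assert mat.loc["d", "b"] == 1 and mat.loc["c", "b"] == 0


def test_compare_networks_summary_consistency():
    ssddn = build_graph(direct=[("a", "b")], nodes="abcd",
                        categories={"a": "x", "b": "x", "c": "y", "d": "y"})
    plus = build_graph(direct=[("a", "b")],
                       indirect=[("a", "b", "HDL"), ("c", "d", "TG"),
                                 ("a", "c", "HDL")],
                       nodes="abcd",
                       categories={"a": "x", "b": "x", "c": "y", "d": "y"})
    s = analysis.compare_networks(ssddn, plus, traits=["HDL", "TG", "ALB"])
    assert s["n_edges_ssddn"] == 1 and s["n_edges_ssddnplus"] == 3
    assert s["n_new_edges"] == 2 and s["n_redundant_indirect_edges"] == 1
    assert s["edge_increase_pct"] == pytest.approx(200.0)
    assert s["connected_nodes_ssddn"] == 2
    assert s["connected_nodes_ssddnplus"] == 4
    assert s["biomarker_contribution"]["ALB"] == {"new_edges": 0,
                                                  "redundant_edges": 0}
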