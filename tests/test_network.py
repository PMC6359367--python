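from __future__ import annotations

import networkx as nx
import pytest

from bcrnet.distance import NeighborPair, neighbors_within
from bcrnet.network import (
    Component,
    build_graph,
    components,
    filter_singletons,
    mst,
    name_components,
)
from bcrnet.repertoire import RepertoireCollection

from oracles import all_spanning_tree_weights, brute_force_components


def coll_of(counts: dict[str, int]) -> RepertoireCollection:
    return RepertoireCollection.from_counts(
        {s: {"wk0": c} for s, c in counts.items()}, timepoints=("wk0",)
    )


def comp(cid, vids, edges=0):
    return Component(component_id=cid, vertex_ids=frozenset(vids), edge_count=edges)


class TestBuildGraph:
    # three sequences with pairwise LDs 1 (AAAA-AAAT), 2 (AAAT-AATT via ld 1? no)
    def test_threshold_filters_edges(self):
        coll = coll_of({"AAAA": 1, "AAAT": 1, "TTTT": 1})
        pairs = neighbors_within(coll, 10)  # LDs: 1, 3, 4
        assert sorted(p.ld for p in pairs) == [1, 3, 4]
        assert build_graph(coll, pairs, 2).number_of_edges() == 1
        assert build_graph(coll, pairs, 3).number_of_edges() == 2
        assert build_graph(coll, pairs, 4).number_of_edges() == 3  # complete

    def test_zero_threshold_gives_edgeless_graph(self):
        coll = coll_of({"AAAA": 1, "AAAT": 1})
        g = build_graph(coll, neighbors_within(coll, 5), 0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2


class TestComponents:
    def test_edgeless_graph_gives_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        comps = components(g)
        assert len(comps) == 5
        assert all(c.n_vertices == 1 and c.edge_count == 0 for c in comps)

    def test_path_graph_is_one_component(self):
        g = nx.path_graph(4)
        (c,) = components(g)
        assert c.n_vertices == 4 and c.edge_count == 3

    def test_two_triangles_match_reachability_oracle(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        comps = components(g)
        oracle = brute_force_components(g.nodes, g.edges)
        assert [c.vertex_ids for c in comps] == oracle
        assert all(c.n_vertices == 3 and c.edge_count == 3 for c in comps)

    def test_components_partition_vertices(self):
        g = nx.gnm_random_graph(30, 25, seed=3)
        comps = components(g)
        all_ids = [v for c in comps for v in c.vertex_ids]
        assert sorted(all_ids) == sorted(g.nodes)
        assert [c.component_id for c in comps] == list(range(1, len(comps) + 1))


class TestFilterSingletons:
    def test_retains_multivertex_components_and_reports_census(self):
        comps = [comp(1, {0, 1}, 1), comp(2, {2}), comp(3, {3, 4, 5}, 2), comp(4, {6})]
        retained, census = filter_singletons(comps)
        assert [c.component_id for c in retained] == [1, 3]
        assert census == {
            "total_components": 4,
            "singleton_components": 2,
            "retained_components": 2,
        }

    def test_all_singletons_gives_empty_set(self):
        retained, census = filter_singletons([comp(1, {0}), comp(2, {1})])
        assert retained == [] and census["retained_components"] == 0

    def test_no_singletons_is_identity(self):
        comps = [comp(1, {0, 1}, 1), comp(2, {2, 3}, 1)]
        retained, census = filter_singletons(comps)
        assert retained == comps and census["singleton_components"] == 0


class TestNameComponents:
    def test_largest_component_gets_id_one(self):
        coll = coll_of({"AAAA": 1, "AAAT": 1, "AATT": 1, "GGGG": 1, "GGGT": 1, "CCCC": 9})
        ids = {v.sequence: v.vertex_id for v in coll}
        comps = [
            comp(1, {ids["GGGG"], ids["GGGT"]}, 1),
            comp(2, {ids["AAAA"], ids["AAAT"], ids["AATT"]}, 2),
            comp(3, {ids["CCCC"]}),
        ]
        named = name_components(comps, coll)
        assert [c.n_vertices for c in named] == [3, 2, 1]
        assert [c.component_id for c in named] == [1, 2, 3]

    def test_size_tie_broken_by_total_read_count_then_sequence(self):
        coll = coll_of({"AAAA": 1, "AAAT": 1, "GGGG": 5, "GGGT": 5, "CCCC": 3, "CCCT": 3})
        ids = {v.sequence: v.vertex_id for v in coll}
        comps = [
            comp(1, {ids["AAAA"], ids["AAAT"]}, 1),  # reads 2, min seq AAAA
            comp(2, {ids["GGGG"], ids["GGGT"]}, 1),  # reads 10 -> wins
            comp(3, {ids["CCCC"], ids["CCCT"]}, 1),  # reads 6
        ]
        named = name_components(comps, coll)
        by_new_id = {c.component_id: min(coll.vertex(v).sequence for v in c.vertex_ids)
                     for c in named}
        assert by_new_id == {1: "GGGG", 2: "CCCC", 3: "AAAA"}

    def test_read_count_tie_broken_lexicographically(self):
        coll = coll_of({"AAAA": 2, "AAAT": 2, "GGGG": 2, "GGGT": 2})
        ids = {v.sequence: v.vertex_id for v in coll}
        comps = [
            comp(1, {ids["GGGG"], ids["GGGT"]}, 1),
            comp(2, {ids["AAAA"], ids["AAAT"]}, 1),
        ]
        named = name_components(comps, coll)
        first = [c for c in named if c.component_id == 1][0]
        assert ids["AAAA"] in first.vertex_ids


class TestMst:
    def test_triangle_tree_weight_is_minimal(self):
        pairs = [NeighborPair(0, 1, 1), NeighborPair(0, 2, 2), NeighborPair(1, 2, 2)]
        tree = mst(comp(1, {0, 1, 2}), pairs)
        assert len(tree) == 2
        weight = sum(p.ld for p in tree)
        assert weight == min(all_spanning_tree_weights([0, 1, 2], pairs)) == 3

    def test_two_vertex_component_is_its_single_edge(self):
        pairs = [NeighborPair(5, 9, 3)]
        assert mst(comp(1, {5, 9}), pairs) == pairs

    def test_path_graph_tree_is_the_path(self):
        pairs = [NeighborPair(0, 1, 1), NeighborPair(1, 2, 1), NeighborPair(2, 3, 1)]
        assert sorted(mst(comp(1, {0, 1, 2, 3}), pairs)) == pairs

    def test_matches_networkx_on_random_weighted_graph(self):
        g = nx.gnm_random_graph(12, 30, seed=5)
        pairs = [
            NeighborPair(*sorted((a, b)), ld=(a * 7 + b * 3) % 5 + 1)
            for a, b in g.edges
        ]
        g2 = nx.Graph()
        g2.add_nodes_from(g.nodes)
        g2.add_weighted_edges_from([(p.vertex_id_a, p.vertex_id_b, p.ld) for p in pairs])
        for nodes in nx.connected_components(g2):
            if len(nodes) < 2:
                continue
            c = comp(1, nodes)
            tree = mst(c, pairs)
            assert len(tree) == len(nodes) - 1
            nx_weight = nx.minimum_spanning_tree(g2.subgraph(nodes)).size(weight="weight")
            assert sum(p.ld for p in tree) == nx_weight

    def test_disconnected_component_raises(self):
        with pytest.raises(ValueError):
            mst(comp(1, {0, 1, 2}), [NeighborPair(0, 1, 1)])


class TestSweepLaws:
    def test_component_count_shrinks_and_edges_grow_with_threshold(self):
        coll = coll_of({s: 1 for s in [
            "AAAAAAAA", "AAAAAAAT", "AAAAAATT", "CCCCCCCC", "CCCCCCCT",
            "GGGGGGGG", "GGGGGGTT", "ACGTACGT",
        ]})
        pairs = neighbors_within(coll, 8)
        prev_components = len(coll) + 1
        prev_edges = -1
        for t in range(1, 9):
            g = build_graph(coll, pairs, t)
            comps = components(g)
            assert len(comps) <= prev_components
            assert g.number_of_edges() >= prev_edges
            assert sum(c.n_vertices for c in comps) == len(coll)
            prev_components, prev_edges = len(comps), g.number_of_edges()
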