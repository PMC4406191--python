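"""Advanced graph queries against independent brute-force oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopaxnet import (
    common_stream,
    merge_networks,
    neighborhood,
    paths_between,
    paths_from_to,
)
from biopaxnet.errors import MergeConflictError, MissingNodeError, PreconditionError

from conftest import (
    adjacency,
    bfs_within,
    make_graph,
    path_union_nodes_edges,
    random_digraph,
    reachable,
)


class TestMerge:
    def test_idempotent(self, toy_l3_graph):
        merged = merge_networks([toy_l3_graph, toy_l3_graph])
        assert set(merged.nodes) == set(toy_l3_graph.nodes)
        assert merged.edge_multiset() == toy_l3_graph.edge_multiset()

    def test_disjoint_union(self):
        g1 = make_graph([("a", "b"), ("b", "c")])
        g2 = make_graph([("x", "y"), ("y", "z")])
        merged = merge_networks([g1, g2])
        assert merged.n_nodes == 6 and merged.n_edges == 4

    def test_shared_node_unified(self):
        g1 = make_graph([("a", "shared")])
        g2 = make_graph([("shared", "b")])
        merged = merge_networks([g1, g2])
        assert merged.n_nodes == 3  # |V1| + |V2| - 1

    def test_class_conflict_raises(self):
        g1 = make_graph([("a", "b")], biopax_class="Protein")
        g2 = make_graph([("a", "c")], biopax_class="SmallMolecule")
        with pytest.raises(MergeConflictError):
            merge_networks([g1, g2])

    def test_associative_commutative(self):
        rng = random.Random(11)
        graphs = [random_digraph(rng, n_max=10) for _ in range(3)]
        a, b, c = graphs
        left = merge_networks([merge_networks([a, b]), c])
        right = merge_networks([a, merge_networks([b, c])])
        swapped = merge_networks([c, b, a])
        assert left.edge_multiset() == right.edge_multiset() == swapped.edge_multiset()
        assert set(left.nodes) == set(right.nodes) == set(swapped.nodes)

    def test_class_sets_rederived(self):
        merged = merge_networks([make_graph([("a", "b")])])
        assert merged.class_set("BioPAX").node_ids() == {"a", "b"}

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=20))
    def test_merge_with_itself_is_identity(self, pairs):
        """Merging any duplicate-free graph with copies of itself changes
        nothing: node set and edge multiset are preserved."""
        edges = [(f"n{a}", f"n{b}") for a, b in pairs if a != b]
        g = make_graph(edges, nodes=[f"n{i}" for i in range(9)])
        merged = merge_networks([g, g, g])
        assert set(merged.nodes) == set(g.nodes)
        assert merged.edge_multiset() == g.edge_multiset()


class TestNeighborhood:
    def test_path_both_directions(self):
        g = make_graph([("a", "b"), ("b", "c")])
        assert set(neighborhood(g, {"b"}, "both").nodes) == {"a", "b", "c"}

    def test_downstream_only(self):
        g = make_graph([("a", "b"), ("b", "c")])
        assert set(neighborhood(g, {"b"}, "downstream").nodes) == {"b", "c"}

    def test_all_seeds_gives_whole_graph(self, toy_l3_graph):
        result = neighborhood(toy_l3_graph, set(toy_l3_graph.nodes), "both")
        assert set(result.nodes) == set(toy_l3_graph.nodes)
        assert result.edge_multiset() == toy_l3_graph.edge_multiset()

    def test_unknown_seed(self, toy_l3_graph):
        with pytest.raises(MissingNodeError):
            neighborhood(toy_l3_graph, {"nope"}, "both")

    def test_undirected_participant_traversed_both_ways(self):
        g = make_graph([("i", "p", "participant", False)])
        assert set(neighborhood(g, {"p"}, "downstream").nodes) == {"i", "p"}


class TestCommonStream:
    def test_diamond_downstream(self, diamond_graph):
        result = common_stream(diamond_graph, {"E1", "E2"}, "downstream",
                               include_paths=False)
        assert set(result.nodes) == {"R", "B"}

    def test_diamond_with_connecting_paths(self, diamond_graph):
        result = common_stream(diamond_graph, {"E1", "E2"}, "downstream")
        assert {"E1", "E2", "C1", "C2", "R", "B"} <= set(result.nodes)

    def test_disjoint_reach_is_empty(self):
        g = make_graph([("a", "x"), ("b", "y")])
        assert common_stream(g, {"a", "b"}, "downstream").n_nodes == 0

    def test_upstream_mirror(self, diamond_graph):
        result = common_stream(diamond_graph, {"C1", "C2"}, "upstream",
                               include_paths=False)
        assert set(result.nodes) == set()  # E1/E2 are private upstreams
        result2 = common_stream(diamond_graph, {"B", "R"}, "upstream",
                                include_paths=False)
        assert "A" in set(result2.nodes)

    def test_requires_two_seeds(self, diamond_graph):
        with pytest.raises(PreconditionError):
            common_stream(diamond_graph, {"E1"}, "downstream")


class TestPaths:
    def test_two_hop_path(self):
        g = make_graph([("a", "m"), ("m", "b")])
        result = paths_between(g, {"a", "b"}, limit=2)
        assert set(result.nodes) == {"a", "m", "b"} and result.n_edges == 2

    def test_limit_one_excludes_long_paths(self):
        g = make_graph([("a", "m"), ("m", "b")])
        assert paths_between(g, {"a", "b"}, limit=1).n_nodes == 0

    def test_mutually_adjacent_seeds(self):
        g = make_graph([("a", "b"), ("b", "a")])
        result = paths_between(g, {"a", "b"}, limit=1)
        assert result.n_edges == 2

    def test_from_to_direction_matters(self):
        g = make_graph([("a", "m"), ("m", "b")])
        fwd = paths_from_to(g, {"a"}, {"b"}, limit=2)
        assert set(fwd.nodes) == {"a", "m", "b"}
        assert paths_from_to(g, {"b"}, {"a"}, limit=2).n_nodes == 0

    def test_source_without_outgoing_edges(self):
        g = make_graph([("a", "b")], nodes=["a", "b", "sink"])
        assert paths_from_to(g, {"sink"}, {"a"}, limit=3).n_nodes == 0

    def test_overlapping_sources_targets_rejected(self):
        g = make_graph([("a", "b")])
        with pytest.raises(PreconditionError):
            paths_from_to(g, {"a"}, {"a", "b"}, limit=2)


class TestOracleEquivalence:
    """Queries must match plain-dict brute-force walks on random graphs."""

    @pytest.mark.parametrize("trial", range(25))
    def test_neighborhood_matches_bfs(self, trial):
        rng = random.Random(1000 + trial)
        g = random_digraph(rng, n_max=30)
        seeds = set(rng.sample(sorted(g.nodes), rng.randint(1, 3)))
        limit = rng.randint(1, 3)
        direction = rng.choice(["both", "upstream", "downstream"])
        result = neighborhood(g, seeds, direction, limit)
        expected = set(seeds)
        dirs = ("downstream", "upstream") if direction == "both" else (direction,)
        for d in dirs:
            adj = adjacency(g, reverse=(d == "upstream"))
            for s in seeds:
                expected |= bfs_within(adj, s, limit)
        assert set(result.nodes) == expected

    @pytest.mark.parametrize("trial", range(25))
    def test_common_stream_matches_reach_intersection(self, trial):
        rng = random.Random(2000 + trial)
        g = random_digraph(rng, n_max=25)
        seeds = set(rng.sample(sorted(g.nodes), 2))
        direction = rng.choice(["upstream", "downstream"])
        result = common_stream(g, seeds, direction, include_paths=False)
        adj = adjacency(g, reverse=(direction == "upstream"))
        expected = set.intersection(*(reachable(adj, s) for s in seeds))
        assert set(result.nodes) == expected

    @pytest.mark.parametrize("trial", range(25))
    def test_paths_between_matches_enumeration(self, trial):
        rng = random.Random(3000 + trial)
        g = random_digraph(rng, n_max=20)
        seeds = set(rng.sample(sorted(g.nodes), 2))
        limit = rng.randint(1, 3)
        result = paths_between(g, seeds, limit)
        pairs = [(s, t) for s in seeds for t in seeds if s != t]
        nodes, edge_idx = path_union_nodes_edges(g, pairs, limit)
        assert set(result.nodes) == nodes
        expected_edges = {(g.edges[i].source, g.edges[i].target, g.edges[i].kind)
                          for i in edge_idx}
        assert {(e.source, e.target, e.kind) for e in result.edges} == expected_edges

    @pytest.mark.parametrize("trial", range(25))
    def test_paths_from_to_matches_enumeration(self, trial):
        rng = random.Random(4000 + trial)
        g = random_digraph(rng, n_max=20)
        ids = sorted(g.nodes)
        sources = set(rng.sample(ids, 2))
        targets = set(rng.sample([n for n in ids if n not in sources], 2))
        limit = rng.randint(1, 3)
        result = paths_from_to(g, sources, targets, limit)
        nodes, _ = path_union_nodes_edges(
            g, [(s, t) for s in sources for t in targets], limit)
        assert set(result.nodes) == nodes


class TestResultProperties:
    @pytest.mark.parametrize("trial", range(10))
    def test_results_are_subgraphs_and_limit_monotone(self, trial):
        rng = random.Random(5000 + trial)
        g = random_digraph(rng, n_max=25)
        seeds = set(rng.sample(sorted(g.nodes), 2))
        previous_nodes: set[str] = set()
        for limit in (1, 2, 3, 4):
            result = paths_between(g, seeds, limit)
            assert set(result.nodes) <= set(g.nodes)
            assert result.edge_multiset() <= g.edge_multiset()
            assert previous_nodes <= set(result.nodes)
            previous_nodes = set(result.nodes)
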