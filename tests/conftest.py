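"""Shared fixtures: parsed toy documents, tiny hand-built graphs, oracles."""

from __future__ import annotations

import random

import pytest

from biopaxnet import TypedGraph, build_graph, read_biopax, toy_documents
from biopaxnet.graph import GraphEdge, GraphNode
from biopaxnet.styles import glyph_for_type


@pytest.fixture(scope="session")
def docs() -> dict[str, str]:
    return toy_documents()


@pytest.fixture(scope="session")
def toy_l3_model(docs):
    return read_biopax(docs["toy_l3"])


@pytest.fixture(scope="session")
def toy_l3_graph(toy_l3_model):
    return build_graph(toy_l3_model)


@pytest.fixture(scope="session")
def diamond_graph(docs):
    return build_graph(read_biopax(docs["diamond"]))


def make_graph(edges: list[tuple], nodes: list[str] | None = None,
               biopax_class: str = "Protein") -> TypedGraph:
    """Build a TypedGraph from (source, target[, kind[, directed]]) tuples."""
    g = TypedGraph()
    ids = set(nodes or [])
    for e in edges:
        ids.update(e[:2])
    for nid in sorted(ids):
        g.nodes[nid] = GraphNode(nid, biopax_class, nid, glyph_for_type(biopax_class))
    for e in edges:
        src, dst = e[0], e[1]
        kind = e[2] if len(e) > 2 else "controlled"
        directed = e[3] if len(e) > 3 else kind != "participant"
        g.edges.append(GraphEdge(src, dst, kind, directed))
    return g


def random_digraph(rng: random.Random, n_max: int = 40) -> TypedGraph:
    """Random directed graph with a sprinkling of undirected edges."""
    n = rng.randint(5, n_max)
    ids = [f"n{i}" for i in range(n)]
    m = rng.randint(n, 2 * n)
    edges = []
    for _ in range(m):
        u, v = rng.sample(ids, 2)
        if rng.random() < 0.15:
            edges.append((u, v, "participant", False))
        else:
            edges.append((u, v, "controlled", True))
    return make_graph(edges, nodes=ids)


# ---- independent oracles (plain-dict graph walks, no networkx) ----

def arcs_of(graph: TypedGraph) -> list[tuple[str, str]]:
    """Directed arc list: undirected edges contribute both directions."""
    arcs = []
    for e in graph.edges:
        arcs.append((e.source, e.target))
        if not e.directed:
            arcs.append((e.target, e.source))
    return arcs


def adjacency(graph: TypedGraph, reverse: bool = False) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for u, v in arcs_of(graph):
        if reverse:
            adj[v].add(u)
        else:
            adj[u].add(v)
    return adj


def bfs_within(adj: dict[str, set[str]], seed: str, limit: int) -> set[str]:
    seen = {seed}
    frontier = {seed}
    for _ in range(limit):
        frontier = {w for v in frontier for w in adj[v]} - seen
        seen |= frontier
    return seen


def reachable(adj: dict[str, set[str]], seed: str) -> set[str]:
    seen: set[str] = set()
    stack = list(adj[seed])
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        stack.extend(adj[v])
    return seen


def simple_node_paths(adj: dict[str, set[str]], src: str, dst: str,
                      limit: int) -> list[list[str]]:
    """All simple paths src -> dst with at most *limit* edges (DFS)."""
    out: list[list[str]] = []

    def walk(path: list[str]) -> None:
        if path[-1] == dst and len(path) > 1:
            out.append(list(path))
            return
        if len(path) - 1 >= limit:
            return
        for w in sorted(adj[path[-1]]):
            if w not in path:
                path.append(w)
                walk(path)
                path.pop()

    walk([src])
    return out


def path_union_nodes_edges(graph: TypedGraph, pairs, limit: int):
    """Oracle for the path queries: nodes and edge indices on simple paths."""
    adj = adjacency(graph)
    keep_nodes: set[str] = set()
    keep_edges: set[int] = set()
    arc_index: dict[tuple[str, str], set[int]] = {}
    for i, e in enumerate(graph.edges):
        arc_index.setdefault((e.source, e.target), set()).add(i)
        if not e.directed:
            arc_index.setdefault((e.target, e.source), set()).add(i)
    for s, t in pairs:
        for path in simple_node_paths(adj, s, t, limit):
            keep_nodes.update(path)
            for u, v in zip(path, path[1:]):
                keep_edges |= arc_index[(u, v)]
    return keep_nodes, keep_edges
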