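"""Local graph queries: merge, neighborhood, common stream, paths.

These reproduce, as offline algorithms over a :class:`TypedGraph`, the
advanced query semantics a cPath2 service evaluates server-side: Get
(merge), Nearest Neighborhood, Common Stream, Paths Between and Paths
From To.  Direction follows the edge conventions of
:mod:`biopaxnet.graph`: directed edges are traversed source->target
(downstream) or target->source (upstream); undirected participant edges
are traversable both ways.

Paths are simple (no repeated nodes) and bounded by ``limit`` edges;
the default limit is 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import MergeConflictError, MissingNodeError, PreconditionError
from .graph import ClassSet, GraphEdge, TypedGraph, build_class_set

DEFAULT_LIMIT = 3

QUERY_KINDS = ("get", "neighborhood", "common-stream", "paths-between", "paths-from-to")


@dataclass
class QuerySpec:
    kind: str
    sources: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    direction: str = "both"
    limit: int = DEFAULT_LIMIT

    def __post_init__(self) -> None:
        if self.kind not in QUERY_KINDS:
            raise PreconditionError(f"unknown query kind {self.kind!r}")
        if self.limit < 1:
            raise PreconditionError("limit must be >= 1")
        if self.kind == "paths-from-to" and not self.targets:
            raise PreconditionError("paths-from-to requires targets")


def run_query(graph: TypedGraph, spec: QuerySpec) -> TypedGraph:
    """Dispatch a :class:`QuerySpec` to the matching operation."""
    if spec.kind == "get":
        return merge_networks([graph])
    if spec.kind == "neighborhood":
        return neighborhood(graph, spec.sources, spec.direction, spec.limit)
    if spec.kind == "common-stream":
        direction = spec.direction if spec.direction != "both" else "downstream"
        return common_stream(graph, spec.sources, direction, spec.limit)
    if spec.kind == "paths-between":
        return paths_between(graph, spec.sources, spec.limit)
    return paths_from_to(graph, spec.sources, spec.targets, spec.limit)


def merge_networks(graphs: list[TypedGraph]) -> TypedGraph:
    """Union of nodes by id and edges by (source, target, kind, directed).

    Nodes sharing an id must agree on BioPAX class; the merged graph's
    class set is re-derived.
    """
    if not graphs:
        raise PreconditionError("merge requires at least one graph")
    merged = TypedGraph()
    conflicts: list[str] = []
    for g in graphs:
        for nid in sorted(g.nodes):
            node = g.nodes[nid]
            existing = merged.nodes.get(nid)
            if existing is None:
                merged.nodes[nid] = node
            elif existing.biopax_class != node.biopax_class:
                conflicts.append(
                    f"{nid}: {existing.biopax_class} vs {node.biopax_class}"
                )
    if conflicts:
        raise MergeConflictError("conflicting classes for node ids: " + "; ".join(conflicts))
    seen: set[tuple] = set()
    for g in graphs:
        for e in g.edges:
            key = (e.source, e.target, e.kind, e.directed)
            if key not in seen:
                seen.add(key)
                merged.edges.append(e)
    merged.class_sets.append(build_class_set(merged))
    return merged


def _check_nodes(graph: TypedGraph, ids: Iterable[str]) -> set[str]:
    ids = set(ids)
    missing = ids - set(graph.nodes)
    if missing:
        raise MissingNodeError(f"unknown node ids: {sorted(missing)}")
    return ids


def _view(graph: TypedGraph, direction: str) -> nx.MultiDiGraph:
    g = graph.to_networkx()
    return g.reverse(copy=False) if direction == "upstream" else g


def _induced(graph: TypedGraph, keep_nodes: set[str],
             keep_edges: set[int] | None = None) -> TypedGraph:
    """Subgraph on *keep_nodes*; all induced edges, or a given edge subset."""
    out = TypedGraph(nodes={n: graph.nodes[n] for n in sorted(keep_nodes)})
    for i, e in enumerate(graph.edges):
        if e.source in keep_nodes and e.target in keep_nodes:
            if keep_edges is None or i in keep_edges:
                out.edges.append(e)
    out.class_sets.append(build_class_set(out))
    return out


def neighborhood(graph: TypedGraph, seeds: set[str], direction: str = "both",
                 limit: int = 1) -> TypedGraph:
    """Induced subgraph on the seeds and everything within *limit* hops.

    ``direction`` is ``downstream`` (follow edges), ``upstream`` (follow
    them backwards) or ``both``.  The default limit of 1 is the
    first-order neighborhood.
    """
    seeds = _check_nodes(graph, seeds)
    if limit < 1:
        raise PreconditionError("limit must be >= 1")
    keep = set(seeds)
    directions = ("downstream", "upstream") if direction == "both" else (direction,)
    for d in directions:
        view = _view(graph, d)
        for seed in seeds:
            lengths = nx.single_source_shortest_path_length(view, seed, cutoff=limit)
            keep.update(lengths)
    return _induced(graph, keep)


def common_stream(graph: TypedGraph, seeds: set[str], direction: str,
                  limit: int = DEFAULT_LIMIT, include_paths: bool = True) -> TypedGraph:
    """Nodes reachable from (or reaching) *every* seed, plus connecting paths.

    The common set is the intersection over seeds of the full
    reachability sets in *direction* (seeds themselves excluded unless
    reached through a cycle).  With ``include_paths`` (default) the
    result also carries, for each seed, the simple paths of length
    <= *limit* from that seed into the common set; otherwise only the
    induced subgraph on the common set is returned.
    """
    seeds = _check_nodes(graph, seeds)
    if len(seeds) < 2:
        raise PreconditionError("common stream requires at least 2 seeds")
    if direction not in ("upstream", "downstream"):
        raise PreconditionError("direction must be 'upstream' or 'downstream'")
    view = _view(graph, direction)
    common: set[str] | None = None
    for seed in sorted(seeds):
        reach = nx.descendants(view, seed)
        # a seed on a cycle is reachable from itself (path length >= 1)
        if any(p == seed or p in reach for p in view.predecessors(seed)):
            reach = reach | {seed}
        common = reach if common is None else (common & reach)
    common = common or set()
    if not include_paths or not common:
        return _induced(graph, common)

    keep_nodes = set(common)
    keep_edges: set[int] = set()
    for seed in sorted(seeds):
        for target in sorted(common):
            for path in nx.all_simple_paths(view, seed, target, cutoff=limit):
                keep_nodes.update(path)
                for u, v in zip(path, path[1:]):
                    for _, data in view.get_edge_data(u, v).items():
                        keep_edges.add(data["index"])
    # induced edges inside the common set are part of the stream itself
    for i, e in enumerate(graph.edges):
        if e.source in common and e.target in common:
            keep_edges.add(i)
    return _induced(graph, keep_nodes, keep_edges)


def _path_union(graph: TypedGraph, view: nx.MultiDiGraph,
                pairs: Iterable[tuple[str, str]], limit: int) -> TypedGraph:
    keep_nodes: set[str] = set()
    keep_edges: set[int] = set()
    for s, t in pairs:
        for path in nx.all_simple_paths(view, s, t, cutoff=limit):
            keep_nodes.update(path)
            for u, v in zip(path, path[1:]):
                for _, data in view.get_edge_data(u, v).items():
                    keep_edges.add(data["index"])
    return _induced(graph, keep_nodes, keep_edges)


def paths_between(graph: TypedGraph, seeds: set[str],
                  limit: int = DEFAULT_LIMIT) -> TypedGraph:
    """Union of directed simple paths of length <= limit between seed pairs."""
    seeds = _check_nodes(graph, seeds)
    if len(seeds) < 2:
        raise PreconditionError("paths-between requires at least 2 seeds")
    if limit < 1:
        raise PreconditionError("limit must be >= 1")
    view = graph.to_networkx()
    pairs = [(s, t) for s in sorted(seeds) for t in sorted(seeds) if s != t]
    return _path_union(graph, view, pairs, limit)


def paths_from_to(graph: TypedGraph, sources: set[str], targets: set[str],
                  limit: int = DEFAULT_LIMIT) -> TypedGraph:
    """Union of directed simple paths source -> target of length <= limit."""
    sources = _check_nodes(graph, sources)
    targets = _check_nodes(graph, targets)
    if not sources or not targets:
        raise PreconditionError("sources and targets must be non-empty")
    if sources & targets:
        raise PreconditionError(
            f"sources and targets overlap: {sorted(sources & targets)}"
        )
    view = graph.to_networkx()
    pairs = [(s, t) for s in sorted(sources) for t in sorted(targets)]
    return _path_union(graph, view, pairs, limit)
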