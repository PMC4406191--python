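"""Interchange formats: GraphML, SIF and class-set files.

GraphML is the canonical graph interchange (read and write, with node
class/glyph attributes, per-edge kind and directedness, and optional
layout coordinates).  SIF is a write-only tabular export for tools that
consume simple interaction lines.  Class-set files carry named node
partitions between networks, so e.g. co-expression cluster membership
can be highlighted on a pathway network that shares node identifiers.

Class-set file syntax (defined by this package): UTF-8, tab-separated,
one assignment per line — ``node_id <TAB> class_set_name <TAB> class``;
``#`` starts a comment line.
"""

from __future__ import annotations

import logging
import os

import networkx as nx
import numpy as np

from .errors import ParseError
from .graph import ClassSet, GraphEdge, GraphNode, TypedGraph, build_class_set
from .layout import LayoutResult
from .styles import glyph_for_type

log = logging.getLogger(__name__)


def write_graphml(graph: TypedGraph, sink, layout: LayoutResult | None = None) -> None:
    """Write GraphML with class, glyph, kind/directedness and layout keys.

    Coordinate keys ``x``/``y`` (and ``z`` for 3D layouts) are emitted
    only when *layout* is given.  Output is deterministic: nodes sorted
    by id, edges in stored order.
    """
    g = nx.MultiDiGraph()
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        attrs = {
            "class": node.biopax_class,
            "label": node.label,
            "shape2d": node.glyph.shape2d,
            "shape3d": node.glyph.shape3d,
            "colour": node.glyph.colour,
        }
        if layout is not None:
            coords = layout.coordinates[nid]
            attrs["x"] = float(coords[0])
            attrs["y"] = float(coords[1])
            if layout.dims == 3:
                attrs["z"] = float(coords[2])
        g.add_node(nid, **attrs)
    for e in graph.edges:
        g.add_edge(e.source, e.target, kind=e.kind, is_directed=e.directed)
    if hasattr(sink, "write"):
        nx.write_graphml(g, sink)
    else:
        nx.write_graphml(g, str(sink))


def read_graphml(source) -> tuple[TypedGraph, LayoutResult | None]:
    """Read GraphML back into a typed graph (inverse of :func:`write_graphml`).

    Foreign GraphML without this package's keys loads with the default
    class ``PhysicalEntity`` (warning logged) and undirected-graph edges
    become undirected ``participant`` edges.
    """
    try:
        g = nx.read_graphml(source, force_multigraph=True)
    except Exception as exc:
        raise ParseError(f"unreadable GraphML: {exc}") from exc
    default_directed = g.is_directed()
    graph = TypedGraph()
    foreign = 0
    for nid, data in sorted(g.nodes(data=True)):
        cls = data.get("class")
        if cls is None:
            cls = "PhysicalEntity"
            foreign += 1
        graph.nodes[str(nid)] = GraphNode(
            id=str(nid),
            biopax_class=cls,
            label=data.get("label", str(nid)),
            glyph=glyph_for_type(cls),
        )
    if foreign:
        log.warning("%d node(s) without a class key defaulted to PhysicalEntity", foreign)
    coords: dict[str, list[float]] = {}
    has_xy = all("x" in d and "y" in d for _, d in g.nodes(data=True)) and g.number_of_nodes() > 0
    dims = 3 if has_xy and all("z" in d for _, d in g.nodes(data=True)) else 2
    for u, v, data in g.edges(data=True):
        graph.edges.append(
            GraphEdge(
                source=str(u),
                target=str(v),
                kind=data.get("kind", "participant"),
                directed=bool(data.get("is_directed", default_directed)),
            )
        )
    graph.class_sets.append(build_class_set(graph))
    result = None
    if has_xy:
        for nid, data in g.nodes(data=True):
            point = [float(data["x"]), float(data["y"])]
            if dims == 3:
                point.append(float(data["z"]))
            coords[str(nid)] = np.array(point)
        result = LayoutResult(coordinates=coords, dims=dims, seed=0, iterations_used=0)
    return graph, result


def write_sif(graph: TypedGraph, sink) -> None:
    """One ``source <TAB> kind <TAB> target`` line per edge, sorted."""
    lines = sorted(f"{e.source}\t{e.kind}\t{e.target}" for e in graph.edges)
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def export_class_sets(graph: TypedGraph, sink) -> None:
    """Write every class set of *graph* as a class-set file."""
    lines = ["# biopaxnet class sets: node_id<TAB>class_set<TAB>class"]
    for cs in graph.class_sets:
        for class_name in sorted(cs.classes):
            for nid in sorted(cs.classes[class_name]):
                lines.append(f"{nid}\t{cs.name}\t{class_name}")
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def import_class_sets(graph: TypedGraph, source) -> tuple[TypedGraph, int]:
    """Attach class sets from a file to *graph*.

    Assignments whose node id is absent from the graph are skipped (and
    counted); returns ``(graph, skipped_count)``.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)
    new_sets: dict[str, ClassSet] = {}
    skipped = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 3 or not all(parts):
            raise ParseError(f"malformed class-set line {lineno}: {line!r}")
        node_id, set_name, class_name = parts
        if node_id not in graph.nodes:
            skipped += 1
            continue
        new_sets.setdefault(set_name, ClassSet(name=set_name)).assign(class_name, node_id)
    if skipped:
        log.warning("skipped %d class-set assignment(s) for unknown node ids", skipped)
    graph.class_sets.extend(new_sets[name] for name in sorted(new_sets))
    return graph, skipped
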