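"""Typed network graphs built from BioPAX models.

Node construction: one node per Pathway, Interaction (all flavours),
PhysicalEntity (all flavours) and Gene element.  EntityReference and
other utility elements annotate entities; they do not become nodes.

Edge construction mirrors how a pathway document hangs together:

========================  =======================================  ========
kind                      from -> to                               directed
========================  =======================================  ========
complex-component         Complex -> each component                yes
member                    entity -> each memberPhysicalEntity      yes
pathway-component         Pathway -> each pathwayComponent         yes
pathway-step              Pathway -> stepProcess, and
                          stepProcess(S) -> stepProcess(next(S))   yes
participant-left          left entity -> Conversion                yes
participant-right         Conversion -> right entity               yes
controller                controller entity -> Control             yes
controlled                Control -> controlled process            yes
participant               Interaction -- participant               no
========================  =======================================  ========

Conversions run left -> reaction -> right and controls run
controller -> control -> controlled, so downstream traversal follows
the direction of biochemical flow; generic participation carries no
orientation and is traversable both ways.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from . import hierarchy
from .errors import PreconditionError, UnsupportedTypeError
from .model import BioPaxElement, BioPaxModel, local_fragment
from .styles import GlyphStyle, glyph_for_type

log = logging.getLogger(__name__)

UNDIRECTED_KINDS = frozenset({"participant"})

EDGE_KINDS = (
    "complex-component",
    "pathway-component",
    "pathway-step",
    "participant-left",
    "participant-right",
    "participant",
    "controller",
    "controlled",
    "member",
)


@dataclass(frozen=True)
class GraphNode:
    id: str
    biopax_class: str
    label: str
    glyph: GlyphStyle


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    kind: str
    directed: bool = True


@dataclass
class ClassSet:
    name: str
    classes: dict[str, set[str]] = field(default_factory=dict)

    def assign(self, class_name: str, node_id: str) -> None:
        self.classes.setdefault(class_name, set()).add(node_id)

    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.classes.values():
            out |= ids
        return out


@dataclass
class TypedGraph:
    nodes: dict[str, GraphNode] = field(default_factory=dict)
    edges: list[GraphEdge] = field(default_factory=list)
    class_sets: list[ClassSet] = field(default_factory=list)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_multiset(self) -> Counter:
        return Counter((e.source, e.target, e.kind, e.directed) for e in self.edges)

    def class_set(self, name: str) -> ClassSet:
        for cs in self.class_sets:
            if cs.name == name:
                return cs
        raise KeyError(name)

    def to_networkx(self) -> nx.MultiDiGraph:
        """Directed traversal view: undirected edges become arc pairs.

        Each arc carries ``kind`` and the index of its originating edge,
        so query results can map arcs back to edges.
        """
        g = nx.MultiDiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid, biopax_class=node.biopax_class, label=node.label)
        for i, e in enumerate(self.edges):
            g.add_edge(e.source, e.target, kind=e.kind, index=i)
            if not e.directed:
                g.add_edge(e.target, e.source, kind=e.kind, index=i)
        return g


def graphs_equal(a: TypedGraph, b: TypedGraph) -> bool:
    """Equality on node ids + classes and the edge multiset."""
    if {n: v.biopax_class for n, v in a.nodes.items()} != {
        n: v.biopax_class for n, v in b.nodes.items()
    }:
        return False
    return a.edge_multiset() == b.edge_multiset()


def _is_node_type(type_name: str) -> bool:
    return any(hierarchy.is_a(type_name, t) for t in hierarchy.NODE_TYPES)


def build_graph(model: BioPaxModel) -> TypedGraph:
    """Convert a Level 3 model into a styled :class:`TypedGraph`.

    Deterministic: elements are visited sorted by URI, node ids are URI
    local fragments (de-duplicated with a numeric suffix), and two builds
    of the same model are identical.
    """
    if model.level != 3:
        raise PreconditionError(f"graph construction requires Level 3, got {model.level}")

    graph = TypedGraph()
    uri_to_id: dict[str, str] = {}
    taken: set[str] = set()
    for el in model.sorted_elements():
        if not _is_node_type(el.biopax_type):
            continue
        nid = local_fragment(el.uri)
        if nid in taken:
            k = 2
            while f"{nid}.{k}" in taken:
                k += 1
            nid = f"{nid}.{k}"
        taken.add(nid)
        uri_to_id[el.uri] = nid
        graph.nodes[nid] = GraphNode(
            id=nid,
            biopax_class=el.biopax_type,
            label=el.label,
            glyph=glyph_for_type(el.biopax_type),
        )

    def emit(src_uri: str, dst_uri: str, kind: str) -> None:
        src, dst = uri_to_id.get(src_uri), uri_to_id.get(dst_uri)
        if src is None or dst is None:
            log.debug("skipping %s edge with non-node endpoint %s -> %s",
                      kind, src_uri, dst_uri)
            return
        if src == dst:
            log.debug("skipping self-loop on %s (%s)", src, kind)
            return
        graph.edges.append(
            GraphEdge(source=src, target=dst, kind=kind,
                      directed=kind not in UNDIRECTED_KINDS)
        )

    for el in model.sorted_elements():
        t = el.biopax_type
        if hierarchy.is_a(t, "Complex"):
            for comp in el.refs("component"):
                emit(el.uri, comp, "complex-component")
        if hierarchy.is_a(t, "PhysicalEntity"):
            for member in el.refs("memberPhysicalEntity"):
                emit(el.uri, member, "member")
        if hierarchy.is_a(t, "Pathway"):
            for comp in el.refs("pathwayComponent"):
                emit(el.uri, comp, "pathway-component")
            for step_uri in el.refs("pathwayOrder"):
                step = model.get(step_uri)
                if step is None or not hierarchy.is_a(step.biopax_type, "PathwayStep"):
                    continue
                for proc in step.refs("stepProcess"):
                    emit(el.uri, proc, "pathway-step")
                for next_uri in step.refs("nextStep"):
                    nxt = model.get(next_uri)
                    if nxt is None:
                        continue
                    for proc in step.refs("stepProcess"):
                        for nproc in nxt.refs("stepProcess"):
                            emit(proc, nproc, "pathway-step")
        if hierarchy.is_a(t, "Interaction"):
            if hierarchy.is_a(t, "Control"):
                for c in el.refs("controller"):
                    emit(c, el.uri, "controller")
                for c in el.refs("controlled"):
                    emit(el.uri, c, "controlled")
                for c in el.refs("cofactor"):
                    emit(el.uri, c, "participant")
            elif hierarchy.is_a(t, "Conversion"):
                for c in el.refs("left"):
                    emit(c, el.uri, "participant-left")
                for c in el.refs("right"):
                    emit(el.uri, c, "participant-right")
                for c in el.refs("participant"):
                    emit(el.uri, c, "participant")
            else:
                for c in el.refs("participant"):
                    emit(el.uri, c, "participant")
                for c in el.refs("product"):  # TemplateReaction output
                    emit(el.uri, c, "participant-right")
                for c in el.refs("template"):
                    emit(c, el.uri, "participant-left")

    graph.class_sets.append(build_class_set(graph))
    return graph


def build_class_set(graph: TypedGraph, name: str = "BioPAX") -> ClassSet:
    """Partition of node ids by their concrete BioPAX class."""
    cs = ClassSet(name=name)
    for nid in sorted(graph.nodes):
        cs.assign(graph.nodes[nid].biopax_class, nid)
    return cs


def count_interactions(model: BioPaxModel, pathway_uri: str) -> int:
    """Distinct interactions reachable through pathwayComponent links.

    Recurses through sub-pathways; each interaction is counted once even
    when shared between sibling pathways.
    """
    el = model.get(pathway_uri)
    if el is None or not hierarchy.is_a(el.biopax_type, "Pathway"):
        raise UnsupportedTypeError(f"{pathway_uri!r} does not resolve to a Pathway")
    seen_pathways: set[str] = set()
    interactions: set[str] = set()

    def visit(uri: str) -> None:
        if uri in seen_pathways:
            return
        seen_pathways.add(uri)
        pw = model.get(uri)
        if pw is None:
            return
        for comp_uri in pw.refs("pathwayComponent"):
            comp = model.get(comp_uri)
            if comp is None:
                continue
            if hierarchy.is_a(comp.biopax_type, "Interaction"):
                interactions.add(comp_uri)
            elif hierarchy.is_a(comp.biopax_type, "Pathway"):
                visit(comp_uri)

    visit(pathway_uri)
    return len(interactions)
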