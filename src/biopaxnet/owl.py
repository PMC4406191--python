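"""BioPAX OWL (RDF/XML) reading, writing, level detection and upgrade.

Documents are parsed with :mod:`rdflib`; the subjects typed in the BioPAX
namespace become :class:`~biopaxnet.model.BioPaxElement` records.  Level 2
documents are recognised by their namespace and upgraded in memory: class
and property names are translated to their Level 3 equivalents and the
``physicalEntityParticipant`` indirection is collapsed so interactions
reference physical entities directly.

Xref utility elements are folded into each entity's ``(db, id)`` pairs at
read time and re-emitted as ``UnificationXref`` nodes on write, so the
model holds pathway content, not RDF plumbing.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass

from lxml import etree
from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import OWL
from rdflib.term import BNode

from . import hierarchy
from .errors import (
    DanglingReferenceError,
    NotBiopaxError,
    ParseError,
    PreconditionError,
    UnsupportedLevelError,
)
from .model import BioPaxElement, BioPaxModel, Ref

log = logging.getLogger(__name__)

BP3_NS = "http://www.biopax.org/release/biopax-level3.owl#"
BP2_NS = "http://www.biopax.org/release/biopax-level2.owl#"
BP1_NS = "http://www.biopax.org/release/biopax-level1.owl#"
BP3 = Namespace(BP3_NS)

_XREF_CLASSES = {
    "Xref", "UnificationXref", "RelationshipXref", "PublicationXref",
    "unificationXref", "relationshipXref", "publicationXref", "xref",
}

#: BioPAX Level 2 class -> Level 3 class.
L2_CLASS_MAP = {
    "protein": "Protein",
    "smallMolecule": "SmallMolecule",
    "complex": "Complex",
    "dna": "Dna",
    "rna": "Rna",
    "physicalEntity": "PhysicalEntity",
    "pathway": "Pathway",
    "pathwayStep": "PathwayStep",
    "interaction": "Interaction",
    "physicalInteraction": "MolecularInteraction",
    "conversion": "Conversion",
    "biochemicalReaction": "BiochemicalReaction",
    "complexAssembly": "ComplexAssembly",
    "transport": "Transport",
    "transportWithBiochemicalReaction": "TransportWithBiochemicalReaction",
    "control": "Control",
    "catalysis": "Catalysis",
    "modulation": "Modulation",
}

#: Level 2 participant wrappers collapsed by the upgrade.
L2_WRAPPER_CLASSES = {"physicalEntityParticipant", "sequenceParticipant"}

#: Level 2 property -> Level 3 property (camelCase).
L2_PROP_MAP = {
    "LEFT": "left",
    "RIGHT": "right",
    "CONTROLLER": "controller",
    "CONTROLLED": "controlled",
    "COFACTOR": "cofactor",
    "COMPONENTS": "component",
    "PARTICIPANTS": "participant",
    "PATHWAY-COMPONENTS": "pathwayComponent",
    "STEP-INTERACTIONS": "stepProcess",
    "NEXT-STEP": "nextStep",
    "NAME": "displayName",
    "SHORT-NAME": "displayName",
    "SYNONYMS": "name",
    "COMMENT": "comment",
    "ORGANISM": "organism",
    "CONTROL-TYPE": "controlType",
    "DIRECTION": "conversionDirection",
}


@dataclass
class OwlDocument:
    """A well-formed RDF/XML document with exactly one BioPAX namespace."""

    text: str
    base_iri: str | None
    namespace: str


def _read_text(source) -> str:
    if hasattr(source, "read"):
        data = source.read()
        return data.decode("utf-8") if isinstance(data, bytes) else data
    if isinstance(source, bytes):
        return source.decode("utf-8")
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read()
    if isinstance(source, str) and source.lstrip().startswith("<"):
        return source
    raise ParseError(f"unreadable source: {source!r}")


def load_document(source) -> OwlDocument:
    """Read *source* into an :class:`OwlDocument`, validating XML shape."""
    text = _read_text(source)
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    # the ontology IRI may appear with or without the trailing '#'
    declared = [ns for ns in (BP3_NS, BP2_NS, BP1_NS) if ns.rstrip("#") in text]
    if not declared:
        raise NotBiopaxError("document declares no BioPAX namespace")
    if len(declared) > 1:
        raise ParseError(f"multiple BioPAX namespaces declared: {declared}")
    base = root.base or root.get("{http://www.w3.org/XML/1998/namespace}base")
    return OwlDocument(text=text, base_iri=base, namespace=declared[0])


def detect_level(doc: OwlDocument) -> int:
    """BioPAX major version of *doc*: 3 or 2; Level 1 is unsupported."""
    if doc.namespace == BP3_NS:
        return 3
    if doc.namespace == BP2_NS:
        return 2
    raise UnsupportedLevelError(f"unsupported BioPAX namespace: {doc.namespace}")


def read_biopax(source, strict: bool = False, upgrade: bool = True) -> BioPaxModel:
    """Parse a BioPAX OWL document into a resolved :class:`BioPaxModel`.

    Level 2 input is upgraded to Level 3 unless ``upgrade=False``.
    ``strict=True`` turns dangling references into errors instead of
    warn-and-placeholder.
    """
    doc = load_document(source)
    level = detect_level(doc)
    ns = doc.namespace

    graph = Graph()
    try:
        graph.parse(data=doc.text, format="xml", publicID=doc.base_iri)
    except Exception as exc:  # rdflib wraps sax errors in various ways
        raise ParseError(f"RDF/XML parse failure: {exc}") from exc

    model = BioPaxModel(level=level, elements={})
    xref_table: dict[str, tuple[str, str]] = {}
    subjects: dict[str, str] = {}  # uri -> raw class name
    for s, t in sorted(graph.subject_objects(RDF.type), key=lambda p: (str(p[0]), str(p[1]))):
        tname = str(t)
        if not tname.startswith(ns):
            continue  # owl:Ontology headers and foreign vocabulary
        subjects[str(s)] = tname[len(ns):]

    db_prop, id_prop = ("db", "id") if level == 3 else ("DB", "ID")
    for uri, raw_type in sorted(subjects.items()):
        if raw_type in _XREF_CLASSES:
            db = graph.value(URIRef(uri), URIRef(ns + db_prop))
            ident = graph.value(URIRef(uri), URIRef(ns + id_prop))
            xref_table[uri] = (str(db or ""), str(ident or ""))
            continue
        if level == 3:
            biopax_type = hierarchy.nearest_supported(raw_type)
            if biopax_type != raw_type:
                log.warning("class %s unsupported; retained as %s", raw_type, biopax_type)
        else:
            biopax_type = raw_type  # normalised later by the upgrade
        el = BioPaxElement(uri=uri, biopax_type=biopax_type)
        for p, o in sorted(graph.predicate_objects(URIRef(uri)),
                           key=lambda po: (str(po[0]), str(po[1]))):
            pname = str(p)
            if not pname.startswith(ns):
                continue
            prop = pname[len(ns):]
            if isinstance(o, Literal):
                el.add(prop, str(o))
            elif isinstance(o, (URIRef, BNode)):
                el.add(prop, Ref(str(o)))
        # canonical form: a single displayName lives on the element record,
        # not in the property map, so write(read(x)) is a fixed point
        primary = "displayName" if level == 3 else "NAME"
        vals = [v for v in el.values(primary) if isinstance(v, str)]
        if len(vals) == 1 and len(el.values(primary)) == 1:
            el.display_name = vals[0]
            del el.properties[primary]
        else:
            for np in ((primary, "standardName", "name") if level == 3
                       else (primary, "SHORT-NAME")):
                fallback = [v for v in el.values(np) if isinstance(v, str)]
                if fallback:
                    el.display_name = fallback[0]
                    break
        model.add(el)

    _fold_xrefs(model, xref_table, xref_prop="xref" if level == 3 else "XREF")
    model.resolve_references(strict=strict)
    if level == 2 and upgrade:
        model = upgrade_to_l3(model)
    return model


def _fold_xrefs(model: BioPaxModel, table: dict[str, tuple[str, str]], xref_prop: str) -> None:
    for el in model.elements.values():
        if xref_prop not in el.properties:
            continue
        kept = []
        for v in el.properties[xref_prop]:
            if isinstance(v, Ref) and v.uri in table:
                el.xrefs.append(table[v.uri])
            else:
                kept.append(v)
        if kept:
            el.properties[xref_prop] = kept
        else:
            del el.properties[xref_prop]


def upgrade_to_l3(model: BioPaxModel) -> BioPaxModel:
    """Translate a Level 2 model to Level 3.

    Class and property names are mapped; participant wrapper elements are
    collapsed so that interactions reference the wrapped physical entity
    directly.  The upgraded model has ``len(original) - n_wrappers``
    elements.
    """
    if model.level != 3 and model.level != 2:
        raise PreconditionError(f"cannot upgrade level {model.level}")
    if model.level == 3:
        raise PreconditionError("model is already Level 3")

    wrapper_target: dict[str, str] = {}
    for el in model.elements.values():
        if el.biopax_type in L2_WRAPPER_CLASSES:
            targets = el.refs("PHYSICAL-ENTITY")
            if targets:
                wrapper_target[el.uri] = targets[0]
            else:
                log.warning("participant wrapper %s has no PHYSICAL-ENTITY", el.uri)
                wrapper_target[el.uri] = el.uri  # keep as-is, degraded

    def resolve(uri: str) -> str:
        seen = set()
        while uri in wrapper_target and uri not in seen:
            seen.add(uri)
            uri = wrapper_target[uri]
        return uri

    upgraded = BioPaxModel(level=3, elements={}, provenance=model.provenance)
    for el in model.sorted_elements():
        if el.uri in wrapper_target:
            continue
        new_type = L2_CLASS_MAP.get(el.biopax_type)
        if new_type is None:
            new_type = hierarchy.nearest_supported(
                el.biopax_type[:1].upper() + el.biopax_type[1:]
            )
            log.warning("L2 class %s unmapped; retained as %s", el.biopax_type, new_type)
        new = BioPaxElement(uri=el.uri, biopax_type=new_type,
                            display_name=el.display_name, xrefs=list(el.xrefs))
        for prop, values in el.properties.items():
            new_prop = L2_PROP_MAP.get(prop, prop)
            for v in values:
                new.add(new_prop, Ref(resolve(v.uri)) if isinstance(v, Ref) else v)
        upgraded.add(new)
    return upgraded


def write_biopax(model: BioPaxModel, sink, strict: bool = False) -> None:
    """Serialise a Level 3 model as RDF/XML.

    The output re-reads into an identical model (URIs, types, properties,
    xref pairs).  ``strict=True`` refuses to write models that contain
    placeholder elements from unresolved references.
    """
    if model.level != 3:
        raise PreconditionError("only Level 3 models are written")
    if strict and model.has_placeholders():
        raise DanglingReferenceError("model contains placeholder elements")

    g = Graph()
    g.bind("bp", BP3)
    g.bind("owl", OWL)
    ontology = URIRef("")
    g.add((ontology, RDF.type, OWL.Ontology))
    g.add((ontology, OWL.imports, URIRef(BP3_NS.rstrip("#"))))

    for el in model.sorted_elements():
        s = URIRef(el.uri)
        g.add((s, RDF.type, BP3[el.biopax_type]))
        for prop in sorted(el.properties):
            for v in el.properties[prop]:
                obj = URIRef(v.uri) if isinstance(v, Ref) else Literal(v)
                g.add((s, BP3[prop], obj))
        if el.display_name and "displayName" not in el.properties:
            g.add((s, BP3["displayName"], Literal(el.display_name)))
        for i, (db, ident) in enumerate(el.xrefs, start=1):
            xuri = URIRef(f"{el.uri}.xref{i}")
            g.add((s, BP3["xref"], xuri))
            g.add((xuri, RDF.type, BP3["UnificationXref"]))
            g.add((xuri, BP3["db"], Literal(db)))
            g.add((xuri, BP3["id"], Literal(ident)))

    data = g.serialize(format="xml")
    if hasattr(sink, "write"):
        sink.write(data if isinstance(data, str) else data.decode("utf-8"))
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(data if isinstance(data, str) else data.decode("utf-8"))


def to_owl_string(model: BioPaxModel) -> str:
    """Serialise to an in-memory RDF/XML string (round-trip convenience)."""
    buf = io.StringIO()
    write_biopax(model, buf)
    return buf.getvalue()
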