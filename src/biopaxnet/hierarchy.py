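"""Supported subset of the BioPAX Level 3 class hierarchy.

The full ontology defines over sixty classes; this package supports the
entity, interaction and utility classes that occur in desk-scale pathway
documents and that map onto network glyphs.  The hierarchy is a rooted
tree: ``is_a`` walks parent links, so queries for an ancestor type (say
``Control``) can transparently cover its flavours (``Catalysis``,
``Modulation``...).

Two structural names, ``Element`` (the root) and ``UtilityClass``, exist
so that every supported class has a single rooted parent chain; they are
not BioPAX entity types themselves but may appear as fallback types for
exotic input classes.
"""

from __future__ import annotations

from functools import lru_cache

from .errors import UnsupportedTypeError

ROOT = "Element"

# child -> parent.  TransportWithBiochemicalReaction is a dual subclass of
# BiochemicalReaction and Transport in the ontology; a single parent is
# required here and the biochemical branch is the one that matters for
# participant semantics (left/right).
PARENTS: dict[str, str | None] = {
    "Element": None,
    "Entity": "Element",
    "Pathway": "Entity",
    "Interaction": "Entity",
    "Control": "Interaction",
    "Catalysis": "Control",
    "Modulation": "Control",
    "TemplateReactionRegulation": "Control",
    "Conversion": "Interaction",
    "BiochemicalReaction": "Conversion",
    "TransportWithBiochemicalReaction": "BiochemicalReaction",
    "ComplexAssembly": "Conversion",
    "Degradation": "Conversion",
    "Transport": "Conversion",
    "TemplateReaction": "Interaction",
    "MolecularInteraction": "Interaction",
    "GeneticInteraction": "Interaction",
    "PhysicalEntity": "Entity",
    "Protein": "PhysicalEntity",
    "SmallMolecule": "PhysicalEntity",
    "Dna": "PhysicalEntity",
    "DnaRegion": "PhysicalEntity",
    "Rna": "PhysicalEntity",
    "RnaRegion": "PhysicalEntity",
    "Complex": "PhysicalEntity",
    "Gene": "Entity",
    "UtilityClass": "Element",
    "EntityReference": "UtilityClass",
    "ProteinReference": "EntityReference",
    "SmallMoleculeReference": "EntityReference",
    "DnaReference": "EntityReference",
    "DnaRegionReference": "EntityReference",
    "RnaReference": "EntityReference",
    "RnaRegionReference": "EntityReference",
    "PathwayStep": "UtilityClass",
    "BiochemicalPathwayStep": "PathwayStep",
}

SUPPORTED_TYPES = frozenset(PARENTS)

#: Types whose instances become graph nodes.
NODE_TYPES = ("Pathway", "Interaction", "PhysicalEntity", "Gene")


def check_type(name: str) -> str:
    if name not in PARENTS:
        raise UnsupportedTypeError(f"unsupported BioPAX type: {name!r}")
    return name


@lru_cache(maxsize=None)
def ancestors(name: str) -> tuple[str, ...]:
    """Parent chain of *name*, inclusive, root last."""
    check_type(name)
    chain = [name]
    while (parent := PARENTS[chain[-1]]) is not None:
        chain.append(parent)
    return tuple(chain)


def is_a(type_name: str, ancestor: str) -> bool:
    """True iff *ancestor* lies on the (inclusive) parent chain of *type_name*."""
    check_type(ancestor)
    return ancestor in ancestors(type_name)


def nearest_supported(name: str, fallback: str = ROOT) -> str:
    """Map an arbitrary class name onto the supported hierarchy.

    Supported names pass through; a few known-but-unsupported BioPAX L3
    utility classes collapse to ``UtilityClass``; anything else becomes
    *fallback* (the root by default).
    """
    if name in PARENTS:
        return name
    if name in _KNOWN_UTILITY:
        return "UtilityClass"
    return fallback


_KNOWN_UTILITY = frozenset(
    {
        "Provenance",
        "BioSource",
        "Stoichiometry",
        "Evidence",
        "Score",
        "ExperimentalForm",
        "SequenceLocation",
        "SequenceInterval",
        "SequenceSite",
        "ChemicalStructure",
        "DeltaG",
        "KPrime",
        "CellularLocationVocabulary",
        "CellVocabulary",
        "TissueVocabulary",
        "EntityReferenceTypeVocabulary",
        "EvidenceCodeVocabulary",
        "ExperimentalFormVocabulary",
        "InteractionVocabulary",
        "PhenotypeVocabulary",
        "RelationshipTypeVocabulary",
        "SequenceModificationVocabulary",
        "SequenceRegionVocabulary",
        "ControlledVocabulary",
    }
)
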