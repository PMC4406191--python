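"""In-memory object model for BioPAX documents.

A :class:`BioPaxModel` is a URI-keyed store of :class:`BioPaxElement`
records.  Property values are either plain literals (``str``) or
:class:`Ref` handles naming another element by URI; after a successful
read every ``Ref`` resolves within the model (or is replaced by a
placeholder, depending on the dangling-reference policy).

Level-2 documents are held with their raw lower-camel class names and
upper-case property names until :func:`biopaxnet.owl.upgrade_to_l3`
normalises them; hierarchy validation therefore only applies at level 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from . import hierarchy
from .errors import DanglingReferenceError, PreconditionError

log = logging.getLogger(__name__)


class Ref(NamedTuple):
    """A reference-valued property entry: points at another element's URI."""

    uri: str


PropertyValue = "str | Ref"


@dataclass
class BioPaxElement:
    uri: str
    biopax_type: str
    properties: dict[str, list] = field(default_factory=dict)
    display_name: str | None = None
    xrefs: list[tuple[str, str]] = field(default_factory=list)

    def add(self, prop: str, value) -> None:
        self.properties.setdefault(prop, []).append(value)

    def values(self, prop: str) -> list:
        return self.properties.get(prop, [])

    def refs(self, prop: str) -> list[str]:
        """URIs of the reference-valued entries of *prop*, in stored order."""
        return [v.uri for v in self.properties.get(prop, []) if isinstance(v, Ref)]

    @property
    def label(self) -> str:
        return self.display_name or local_fragment(self.uri)

    def __repr__(self) -> str:  # compact: models can hold many elements
        return f"<{self.biopax_type} {self.uri}>"


@dataclass
class BioPaxModel:
    level: int = 3
    elements: dict[str, BioPaxElement] = field(default_factory=dict)
    provenance: str | None = None

    def add(self, element: BioPaxElement) -> BioPaxElement:
        if element.uri in self.elements:
            raise PreconditionError(f"duplicate element URI: {element.uri}")
        self.elements[element.uri] = element
        return element

    def new(self, uri: str, biopax_type: str, **props) -> BioPaxElement:
        """Convenience constructor used by fixtures and the generator."""
        if self.level == 3:
            hierarchy.check_type(biopax_type)
        el = BioPaxElement(uri=uri, biopax_type=biopax_type)
        for prop, values in props.items():
            if isinstance(values, Ref) or not isinstance(values, (list, tuple)):
                values = [values]
            for v in values:
                el.add(prop, v)
        return self.add(el)

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, uri: str) -> bool:
        return uri in self.elements

    def __getitem__(self, uri: str) -> BioPaxElement:
        return self.elements[uri]

    def get(self, uri: str) -> BioPaxElement | None:
        return self.elements.get(uri)

    def sorted_elements(self) -> Iterator[BioPaxElement]:
        """Deterministic iteration order: sorted by URI."""
        for uri in sorted(self.elements):
            yield self.elements[uri]

    def resolve_references(self, strict: bool = False) -> list[str]:
        """Ensure every Ref points at an element of this model.

        Dangling URIs either raise (*strict*) or gain a placeholder
        element of the root physical-entity type, mirroring how
        truncated aggregated exports are usually handled.  Returns the
        list of URIs that were dangling.
        """
        dangling: list[str] = []
        for el in list(self.elements.values()):
            for values in el.properties.values():
                for v in values:
                    if isinstance(v, Ref) and v.uri not in self.elements:
                        dangling.append(v.uri)
        if dangling:
            if strict:
                raise DanglingReferenceError(
                    f"unresolved references: {sorted(set(dangling))}"
                )
            for uri in sorted(set(dangling)):
                log.warning("dangling reference %s -> placeholder element", uri)
                placeholder = BioPaxElement(uri=uri, biopax_type="PhysicalEntity")
                placeholder.add("comment", "placeholder for unresolved reference")
                self.elements[uri] = placeholder
        return sorted(set(dangling))

    def has_placeholders(self) -> bool:
        return any(
            "placeholder for unresolved reference" in el.values("comment")
            for el in self.elements.values()
        )


def local_fragment(uri: str) -> str:
    """Local name of a URI: text after '#', else after the last '/'."""
    if "#" in uri:
        return uri.rsplit("#", 1)[1] or uri
    return uri.rstrip("/").rsplit("/", 1)[-1] or uri


def get_elements_of_type(
    model: BioPaxModel, type_name: str, include_subtypes: bool = True
) -> list[BioPaxElement]:
    """Elements of *type_name* (optionally with subtypes), sorted by URI."""
    hierarchy.check_type(type_name)
    if include_subtypes:
        keep = lambda t: hierarchy.is_a(t, type_name)  # noqa: E731
    else:
        keep = lambda t: t == type_name  # noqa: E731
    return [el for el in model.sorted_elements() if keep(el.biopax_type)]
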