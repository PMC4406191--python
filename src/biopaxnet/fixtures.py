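"""Hand-authored toy BioPAX documents shipped with the package.

Four fixtures cover the pipeline's corner cases without any download:

``toy_l3``
    One pathway, two biochemical reactions, four proteins, a two-member
    complex and three protein references (11 elements, 8-node graph).
``toy_l2``
    The same pathway authored in BioPAX Level 2 with
    ``physicalEntityParticipant`` wrappers; after the upgrade its graph
    is identical to ``toy_l3``'s.
``diamond``
    Two enzymes catalysing one reaction — the common-stream diamond.
``nested``
    A pathway containing a reaction plus a sub-pathway of two reactions
    (recursive interaction count 3), and an empty pathway.
"""

from __future__ import annotations

from importlib import resources

FIXTURE_NAMES = ("toy_l3", "toy_l2", "diamond", "nested")


def fixture_text(name: str) -> str:
    """OWL text of a named fixture."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")
    return resources.files("biopaxnet.data").joinpath(f"{name}.owl").read_text("utf-8")


def toy_documents() -> dict[str, str]:
    """All shipped fixtures as ``{name: OWL text}``."""
    return {name: fixture_text(name) for name in FIXTURE_NAMES}
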