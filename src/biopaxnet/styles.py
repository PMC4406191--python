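"""Glyph styling: BioPAX type -> mEPN-derived 2D/3D shapes and colour.

The style table ships as a versioned YAML data file so a fuller palette
can be dropped in without code changes; types missing from the table
inherit the style of their nearest styled ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from . import hierarchy


@dataclass(frozen=True)
class GlyphStyle:
    shape2d: str
    shape3d: str
    colour: str


@lru_cache(maxsize=1)
def default_style_table() -> dict[str, GlyphStyle]:
    text = resources.files("biopaxnet.data").joinpath("styles.yaml").read_text("utf-8")
    raw = yaml.safe_load(text)
    return {
        name: GlyphStyle(entry["shape2d"], entry["shape3d"], entry["colour"])
        for name, entry in raw.items()
    }


def glyph_for_type(type_name: str, table: dict[str, GlyphStyle] | None = None) -> GlyphStyle:
    """Style for *type_name*, inheriting from the nearest styled ancestor."""
    table = table if table is not None else default_style_table()
    for ancestor in hierarchy.ancestors(type_name):  # walks child -> root
        if ancestor in table:
            return table[ancestor]
    raise KeyError(f"no style reachable for {type_name!r}")  # root is always styled
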