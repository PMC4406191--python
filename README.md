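# biopaxnet

**BioPAX pathways as typed, styled, laid-out networks.**

Pathway and molecular-interaction knowledge is exchanged in BioPAX, an
OWL ontology serialised as RDF/XML, and aggregated at scale by services
such as Pathway Commons.  `biopaxnet` is a library and command-line tool
for people who want that knowledge as a *network*: it parses BioPAX
Level 2/3 documents (Level 2 is upgraded in memory), converts them to a
typed graph with mEPN-derived glyph styling, runs the advanced graph
queries offered by cPath2-style services locally and offline, computes
2D/3D force-directed layouts, and exchanges results as GraphML, SIF and
class-set files.  A fully mockable cPath2 client covers search, fetch
and traverse against a live service.

## The model in brief

* **Graph construction.**  Every Pathway, Interaction, PhysicalEntity
  and Gene element becomes one node (entity references and other utility
  elements annotate nodes, they do not become nodes).  Edges encode
  complex membership (`Complex → component`), pathway membership and
  step order (`Pathway → pathwayComponent`, step links), and interaction
  participation: a Conversion runs `left → reaction → right`, a Control
  runs `controller → control → controlled`, and generic participation is
  undirected.  Each node carries a glyph (2D shape, 3D solid, colour)
  from a versioned style table keyed by BioPAX type, with unlisted
  subtypes inheriting their nearest styled ancestor — e.g. the dumbbell
  for RNA regions and the Ion/Simple Molecule glyph for small molecules.
  A "BioPAX" class set partitions the nodes by concrete entity type.

* **Queries.**  Nearest neighborhood (bounded BFS), common stream (the
  intersection of per-seed reachability, optionally with connecting
  paths), and paths-between / paths-from-to (unions of simple directed
  paths of bounded length ≤ *limit*, default 3), all defined over the
  edge directions above.

* **Layout.**  A multilevel spring embedder in the FMMM family:
  matching-based coarsening, seeded random placement of the coarsest
  level, then per-level refinement under attraction `F_a = d²/ℓ` along
  edges and truncated repulsion `F_r = ℓ²/d` for pairs closer than
  `R = 3ℓ`, with an energy accept/reject step so total energy never
  increases across sweeps.  An isolated connected pair equilibrates at
  exactly `d = ℓ`.

## Worked example

```python
from biopaxnet import build_graph, common_stream, fixture_text, read_biopax

model = read_biopax(fixture_text("diamond"))
graph = build_graph(model)
print(graph.n_nodes, graph.n_edges)
# 7 6   — two enzymes, two catalyses, one reaction, substrate and product

stream = common_stream(graph, {"E1", "E2"}, "downstream", include_paths=False)
print(sorted(stream.nodes))
# ['B', 'R'] — the reaction and its product are downstream of *both* enzymes
```

The seven nodes are the enzymes E1/E2, their control nodes C1/C2, the
reaction R and metabolites A/B; the common-stream query returns exactly
the part of the network both enzymes can influence.  The `examples/`
directory has one short script per capability (parsing, Level 2
upgrade, queries, layout, the offline client, the model generator);
each prints the numbers it computes and what they mean.

The same pipeline is available from the shell:

```sh
biopaxnet convert pathway.owl --out pathway.graphml --sif pathway.sif
biopaxnet layout pathway.graphml --dims 3 --seed 42 --out pathway.layout.graphml
biopaxnet query pathway.owl --kind paths-between --seed P1 --seed P2 --limit 3 --out sub.graphml
biopaxnet gen --spec spec.yaml --seed 7 --out model.owl
```

## Scope

No interactive GUI or rendering, no OWL reasoning, no BioPAX Level 1,
no SBGN/Cytoscape session export, and no gene co-expression analysis.
Species names come from a small bundled taxonomy table (pluggable
resolver) rather than a live lookup.
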