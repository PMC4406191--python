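# Methods

## Supported ontology subset

BioPAX Level 3 defines over sixty classes; `biopaxnet` supports the
entity, interaction and utility classes that occur in desk-scale pathway
documents: Pathway; Interaction with the Control (Catalysis, Modulation,
TemplateReactionRegulation), Conversion (BiochemicalReaction,
TransportWithBiochemicalReaction, ComplexAssembly, Degradation,
Transport), TemplateReaction, MolecularInteraction and
GeneticInteraction branches; PhysicalEntity with Protein, SmallMolecule,
Dna/DnaRegion, Rna/RnaRegion and Complex; Gene; EntityReference and its
flavours; PathwayStep/BiochemicalPathwayStep.  The hierarchy is a rooted
tree with two structural names (`Element`, `UtilityClass`) so every
class has a single parent chain.  `TransportWithBiochemicalReaction` is
a dual subclass in the ontology; here it is parented under
`BiochemicalReaction`, the branch that carries left/right participant
semantics.  Classes outside the subset degrade gracefully: known
utility classes collapse to `UtilityClass`, anything else to the root,
with a warning — documents are never rejected for exotic vocabulary.

## Reading, writing and the Level 2 upgrade

Documents are parsed with rdflib; subjects typed in the BioPAX namespace
become model elements, literal objects become string properties and
resource objects become references.  Xref utility elements are folded
into each entity's `(db, id)` pairs at read time and re-emitted as
`UnificationXref` nodes on write; a single `displayName` likewise lives
on the element record rather than in the property map.  This canonical
form makes serialisation a fixed point: `write(read(write(m))) ==
write(m)` byte-for-byte, which the tests assert on fixtures and
generated models.

Dangling references (common in truncated aggregated exports) default to
warn-and-placeholder — a `PhysicalEntity` stub marked by a comment — and
can be escalated to hard errors with `strict=True`; strict mode also
refuses to serialise models containing placeholders.

Level 2 documents are recognised by namespace and upgraded before graph
construction: class names map to their Level 3 equivalents
(`protein → Protein`, `biochemicalReaction → BiochemicalReaction`, ...),
upper-case property names map to Level 3 camelCase (`LEFT → left`,
`PATHWAY-COMPONENTS → pathwayComponent`, ...), and the
`physicalEntityParticipant` indirection is collapsed so interactions
reference physical entities directly.  The upgraded model has exactly
`len(original) − n_wrappers` elements, and the Level 2 toy fixture
builds a graph identical to its hand-authored Level 3 twin.

## Graph construction

One node per Pathway, Interaction, PhysicalEntity or Gene element; node
ids are URI local fragments, de-duplicated with a numeric suffix, and
element iteration is sorted by URI, so construction is deterministic.
Edge kinds and directions:

| kind | from → to | directed |
|---|---|---|
| complex-component | Complex → component | yes |
| member | entity → memberPhysicalEntity | yes |
| pathway-component | Pathway → pathwayComponent | yes |
| pathway-step | Pathway → stepProcess; stepProcess(S) → stepProcess(next(S)) | yes |
| participant-left | left entity → Conversion | yes |
| participant-right | Conversion → right entity | yes |
| controller | controller entity → Control | yes |
| controlled | Control → controlled process | yes |
| participant | Interaction — participant | no |

Conversions run left → reaction → right and controls run controller →
control → controlled so that downstream traversal follows biochemical
flow; this is also what gives the common-stream query its meaning.
PathwayStep elements contribute edges only — the pathway links to each
step's processes, and consecutive steps link their processes pairwise —
since steps are ordering scaffolding, not biological entities.
Self-loops are suppressed at construction.  Class sets record the
*concrete* type of each node (a Catalysis is classed `Catalysis`, not
`Control`), so type breakdowns stay sharp.

Interaction counting for a pathway recurses through sub-pathway
components with a visited set (cycle-safe) and counts distinct
interactions once, mirroring the traverse path
`Pathway/pathwayComponent*:Interaction` used by the client.

## Glyph styling

The style table ships as YAML (type → 2D shape, 3D solid, colour) so a
fuller palette can be dropped in without code changes.  Types missing
from the table inherit the nearest styled ancestor.  Fixed points of the
scheme: the dumbbell glyph for `RnaRegion`, the Ion/Simple Molecule
glyph for `SmallMolecule`, and a dedicated generic-control glyph for
`Control` distinct from its siblings and parent; the remaining entries
are this package's own mEPN-flavoured choices.

## Queries

All queries are local algorithms over the typed graph (networkx
underneath) and return subgraphs of their input.  Undirected participant
edges are traversable both ways; directed edges follow or oppose their
orientation depending on the requested direction.  Neighborhood is
breadth-first within `limit` hops (default 1, the first-order
neighborhood).  Common stream intersects full per-seed reachability —
a seed on a cycle counts as reaching itself — and by default also
returns the simple paths (≤ `limit` edges) connecting each seed to the
common set; `include_paths=False` restricts the result to the common
set.  The path queries union all simple directed paths of length ≤
`limit` between seed pairs (ordered pairs for paths-between, source ×
target pairs for paths-from-to).  `limit` defaults to 3.  Merging
unions nodes by id and edges by (source, target, kind, directedness)
and fails loudly when the same id carries two different BioPAX classes.

Each query is verified against an independent brute-force oracle
(plain-dict BFS, reachability closure, exhaustive DFS path enumeration)
on batches of seeded random graphs.

## Layout

A multilevel spring embedder in the FMMM family, implemented as
coarsening + refinement rather than a multipole expansion — the same
asymptotics at desk scale, with no claim of coordinate compatibility
with other FMMM implementations.

* **Coarsening:** repeated matching-based merging (first unmatched
  neighbour, deterministic order) until ≤ `stop_size` nodes (default 8)
  or no pair can be matched.  A path of 8 nodes coarsens 8 → 4 → 2.
* **Forces:** attraction `F_a = d²/ℓ` along edges, repulsion
  `F_r = ℓ²/d` truncated at `R = 3ℓ`.  The truncation is what makes the
  grid acceleration exact: only pairs in neighbouring grid cells of side
  `R` interact, giving near-linear work per sweep at bounded density
  (dense pairwise evaluation is used below ~600 nodes — identical
  physics, simpler code).  A connected pair in isolation equilibrates at
  `d = ℓ` exactly, the closed form the tests check to 5%.
* **Energy:** `E = Σ_edges d³/3ℓ + Σ_{d<R} ℓ² ln(R/d)`.  Each sweep is
  accept/reject on E: accepted sweeps cool the temperature (maximum
  per-node displacement) by 0.95, rejected sweeps revert and halve it.
  Energy is therefore non-increasing across sweeps *by construction*,
  not by hope in a schedule.
* **Determinism:** the only randomness is the seeded coarsest-level
  placement (uniform in a cube of side `ℓ√n`) and the seeded jitter at
  prolongation; the same seed reproduces coordinates bit-exactly.
  Defaults: `ℓ = 1`, tolerance `10⁻³ℓ` on maximum displacement, 120
  sweeps per level.  Final coordinates are origin-centred.

## Pathway Commons client

All network access goes through an injectable transport object; the
default live transport uses stdlib urllib and the test suite uses
canned responses, so nothing in the package ever requires a connection.
Request construction is a pure function of the query — keywords (with
Boolean operators, `field:term` pairs and `*` wildcards) pass through
verbatim, `name_only` wraps them as `name:(...)`, TopPathways dispatches
to its dedicated endpoint — which makes the exact URLs snapshot-
testable.  Pages hold at most 500 hits and the pagination iterator
issues exactly ⌈total/500⌉ requests.  Species names resolve from a
small bundled NCBI taxonomy table through a pluggable resolver hook
instead of a live lookup.  Advanced queries run in `local` mode by
default (fetch per-hit OWL, build, merge, query locally); `remote` mode
issues the corresponding service `graph`/`get` request and parses the
returned OWL.

## Synthetic models

The generator emulates a desk-scale slice of an aggregated pathway
database: proteins and small molecules feed complexes (≥ 2 members,
size ~ N(mean, 1) clamped to the pool), reactions draw one left and one
right participant from a reshuffled bag (so small pools spread across
reactions rather than repeating), a configurable fraction of reactions
receives a Catalysis with a random protein controller, and reactions
are partitioned across pathways with optional sub-pathway nesting.
Defaults (2 pathways, 8 reactions, 10 proteins, 3 small molecules, 2
complexes of mean size 2.5, 25% controlled) give a connected, sparse,
heterogeneous model of the size a single Pathway Commons record
typically yields.  Expected node/edge counts per kind and per-pathway
interaction counts are recorded *during* generation, so a builder bug
cannot cancel against a recount; the independent cross-check is the set
of hand-derived fixtures.  The generator does not model realistic
topology (hubs, degree distributions, entity reuse across pathways), so
passing tests certify construction and query correctness, not
robustness to the statistical structure of real interactomes.

Infeasible specifications (complexes without a pool, reactions with
fewer than two candidate participants, control without proteins) are
rejected up front.

## Interchange

GraphML carries node class/label/glyph attributes, per-edge kind and
directedness, and optional x/y/z layout coordinates (z only for 3D);
reading is the inverse of writing, and foreign GraphML without these
keys loads with the default class `PhysicalEntity` and a warning.  SIF
is write-only, one sorted `source TAB kind TAB target` line per edge,
byte-identical across runs.  Class-set files are tab-separated
`node_id / class_set / class` lines with `#` comments; import attaches
new class sets to a graph, skipping (and counting) ids the graph does
not contain — the mechanism for highlighting, say, co-expression
clusters on a pathway network that shares identifiers.  Import returns
the skip count alongside the graph so callers can surface it.

## Known limitations

* The style table beyond the three fixed glyph mappings is a placeholder
  palette, intended to be replaced by a full transcription of an mEPN
  scheme.
* The Level 2 upgrade covers the supported subset's classes and the
  common property vocabulary, not the full Level 2 specification.
* Layout quality is tuned for sparse pathway graphs; very dense graphs
  spend the sweep budget before reaching the displacement tolerance.
* `remote` advanced queries trust the service to apply query semantics;
  only `local` mode is oracle-checked.

## Problem sizes used in the checks

The construction oracle runs 200 generated models of up to ~300
elements; the query oracles run 100 random directed graphs of up to 40
nodes with limits 1–3; round trips cover all fixtures plus a generated
model; layout checks use dyads and fixture-scale graphs.  These sizes
exercise every code path (including the coarsening hierarchy and both
repulsion evaluation strategies) while keeping the default test run
fast.
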