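"""Seeded generator of random BioPAX Level 3 models with known composition.

The generator emulates a desk-scale slice of an aggregated pathway
database: a handful of pathways partitioning biochemical reactions whose
participants are drawn from a pool of proteins, small molecules and
complexes, with a configurable share of reactions under catalytic
control and optional sub-pathway nesting.  It records exact expected
node and edge counts *during* generation (not by re-walking the model),
so the graph builder can be checked against independent bookkeeping.

It does not attempt statistically realistic topology (degree
distributions, hub proteins, cross-pathway reuse); it provides known
ground truth, not biology.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field

from .errors import GeneratorSpecError
from .model import BioPaxModel, Ref

BASE = "http://biopaxnet.example/gen#"


@dataclass
class GeneratorSpec:
    n_pathways: int = 2
    n_reactions: int = 8
    n_proteins: int = 10
    n_small_molecules: int = 3
    n_complexes: int = 2
    mean_complex_size: float = 2.5
    control_fraction: float = 0.25
    nesting_depth: int = 0
    seed: int = 42

    def validate(self) -> None:
        counts = (self.n_pathways, self.n_reactions, self.n_proteins,
                  self.n_small_molecules, self.n_complexes, self.nesting_depth)
        if any(c < 0 for c in counts):
            raise GeneratorSpecError("all counts must be >= 0")
        if not 0.0 <= self.control_fraction <= 1.0:
            raise GeneratorSpecError("control_fraction must be in [0, 1]")
        pool = self.n_proteins + self.n_small_molecules
        if self.n_complexes > 0 and pool < 2:
            raise GeneratorSpecError("complexes need at least 2 member entities")
        if self.n_complexes > 0 and self.mean_complex_size > pool:
            raise GeneratorSpecError("mean complex size exceeds the entity pool")
        if self.n_reactions > 0 and pool + self.n_complexes < 2:
            raise GeneratorSpecError("reactions need at least 2 participant entities")
        if (self.control_fraction > 0 and self.n_reactions > 0
                and round(self.control_fraction * self.n_reactions) > 0
                and self.n_proteins == 0):
            raise GeneratorSpecError("catalytic control requires proteins")


@dataclass
class ExpectedCounts:
    """Ground truth recorded while the model was generated."""

    nodes_by_class: Counter = field(default_factory=Counter)
    edges_by_kind: Counter = field(default_factory=Counter)
    interactions_per_pathway: dict[str, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return sum(self.nodes_by_class.values())

    @property
    def n_edges(self) -> int:
        return sum(self.edges_by_kind.values())


def generate_model(spec: GeneratorSpec) -> tuple[BioPaxModel, ExpectedCounts]:
    """Build a random Level 3 model and its exact expected graph counts."""
    spec.validate()
    rng = random.Random(spec.seed)
    model = BioPaxModel(level=3, provenance=f"biopaxnet generator seed={spec.seed}")
    expected = ExpectedCounts()

    proteins = [f"{BASE}Protein_{i+1}" for i in range(spec.n_proteins)]
    smols = [f"{BASE}SmallMolecule_{i+1}" for i in range(spec.n_small_molecules)]
    for uri in proteins:
        el = model.new(uri, "Protein")
        el.display_name = "P" + uri.rsplit("_", 1)[-1]
    for uri in smols:
        model.new(uri, "SmallMolecule")
    expected.nodes_by_class["Protein"] = len(proteins)
    if smols:
        expected.nodes_by_class["SmallMolecule"] = len(smols)

    member_pool = proteins + smols
    complexes = []
    for i in range(spec.n_complexes):
        uri = f"{BASE}Complex_{i+1}"
        size = int(round(rng.normalvariate(spec.mean_complex_size, 1.0)))
        size = max(2, min(len(member_pool), size))
        components = sorted(rng.sample(member_pool, size))
        model.new(uri, "Complex", component=[Ref(c) for c in components])
        complexes.append(uri)
        expected.edges_by_kind["complex-component"] += size
    if complexes:
        expected.nodes_by_class["Complex"] = len(complexes)

    # reactions draw left/right from a reshuffled bag so small pools get
    # spread across reactions instead of repeating the same entity
    participant_pool = member_pool + complexes
    bag: list[str] = []

    def draw(exclude: str | None = None) -> str:
        nonlocal bag
        while True:
            if not bag:
                bag = list(participant_pool)
                rng.shuffle(bag)
            candidate = bag.pop()
            if candidate != exclude:
                return candidate

    reactions = []
    for i in range(spec.n_reactions):
        uri = f"{BASE}Reaction_{i+1}"
        left = draw()
        right = draw(exclude=left)
        model.new(uri, "BiochemicalReaction", left=Ref(left), right=Ref(right))
        reactions.append(uri)
    if reactions:
        expected.nodes_by_class["BiochemicalReaction"] = len(reactions)
        expected.edges_by_kind["participant-left"] = len(reactions)
        expected.edges_by_kind["participant-right"] = len(reactions)

    n_controlled = round(spec.control_fraction * spec.n_reactions)
    for i, reaction in enumerate(sorted(rng.sample(reactions, n_controlled))):
        uri = f"{BASE}Catalysis_{i+1}"
        controller = rng.choice(proteins)
        model.new(uri, "Catalysis", controller=Ref(controller), controlled=Ref(reaction))
    if n_controlled:
        expected.nodes_by_class["Catalysis"] = n_controlled
        expected.edges_by_kind["controller"] = n_controlled
        expected.edges_by_kind["controlled"] = n_controlled

    pathways = [f"{BASE}Pathway_{i+1}" for i in range(spec.n_pathways)]
    direct: dict[str, list[str]] = {p: [] for p in pathways}
    if pathways:
        for reaction in reactions:
            direct[rng.choice(pathways)].append(reaction)
    sub_of: dict[str, str] = {}
    chain_len = min(spec.nesting_depth, max(len(pathways) - 1, 0))
    for i in range(chain_len):
        sub_of[pathways[i]] = pathways[i + 1]  # pathway i contains pathway i+1
    for p in pathways:
        components = [Ref(r) for r in direct[p]]
        if p in sub_of:
            components.append(Ref(sub_of[p]))
        model.new(p, "Pathway", pathwayComponent=components)
        expected.edges_by_kind["pathway-component"] += len(components)
    if pathways:
        expected.nodes_by_class["Pathway"] = len(pathways)

    def recursive_count(p: str, seen: set[str]) -> int:
        if p in seen:
            return 0
        seen.add(p)
        total = len(direct[p])
        if p in sub_of:
            total += recursive_count(sub_of[p], seen)
        return total

    for p in pathways:
        expected.interactions_per_pathway[p] = recursive_count(p, set())

    expected.edges_by_kind += Counter()  # drop zero entries
    return model, expected
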