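"""Generate random pathway models with known composition.

The generator records exact expected node/edge counts while it builds
the model, giving an independent check on graph construction.
"""

from collections import Counter

from biopaxnet import GeneratorSpec, build_graph, count_interactions, generate_model

spec = GeneratorSpec(n_pathways=2, n_reactions=10, n_proteins=12,
                     n_small_molecules=4, n_complexes=2,
                     control_fraction=0.3, nesting_depth=1, seed=7)
model, expected = generate_model(spec)
print(f"generated {len(model)} elements "
      f"({expected.n_nodes} graph nodes, {expected.n_edges} edges expected)")

graph = build_graph(model)
print(f"built graph: {graph.n_nodes} nodes, {graph.n_edges} edges")
print("nodes per class match bookkeeping:",
      Counter(n.biopax_class for n in graph.nodes.values()) == expected.nodes_by_class)
print("edges per kind match bookkeeping:",
      Counter(e.kind for e in graph.edges) == expected.edges_by_kind)

for uri, count in expected.interactions_per_pathway.items():
    got = count_interactions(model, uri)
    name = uri.rsplit("#", 1)[-1]
    print(f"  {name}: {got} interactions (expected {count})")
# Pathway_1 contains Pathway_2, so its count includes the nested reactions.
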