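"""Advanced graph queries on a control/conversion diamond.

The diamond fixture has two enzymes E1, E2 catalysing (via control nodes
C1, C2) the same reaction R that converts A to B, so downstream flow is
E1 -> C1 -> R -> B and E2 -> C2 -> R -> B.
"""

from biopaxnet import (
    build_graph,
    common_stream,
    fixture_text,
    neighborhood,
    paths_from_to,
    read_biopax,
)

graph = build_graph(read_biopax(fixture_text("diamond")))
print(f"diamond graph: {graph.n_nodes} nodes, {graph.n_edges} edges")

hood = neighborhood(graph, {"R"}, direction="both", limit=1)
print(f"first-order neighborhood of R: {sorted(hood.nodes)}")
# Everything one hop from the reaction: both control nodes and both metabolites.

stream = common_stream(graph, {"E1", "E2"}, "downstream", include_paths=False)
print(f"common downstream of E1 and E2: {sorted(stream.nodes)}")
# {B, R}: the reaction and its product are reachable from *both* enzymes.

paths = paths_from_to(graph, {"E1"}, {"B"}, limit=3)
print(f"paths E1 -> B (<= 3 edges): {sorted(paths.nodes)}, {paths.n_edges} edges")
# The single route E1 -> C1 -> R -> B.
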