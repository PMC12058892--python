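"""The neighbor graph of a preference structure.

States at symmetric-difference distance 2 (one flipped pair) are
neighbors; the six linear orders on three options form a 6-cycle.  The
graph exports to DOT and GraphML for external layout tools.
"""

from korders import (
    PairUniverse,
    PreferenceStructure,
    all_relations,
    structure_graph,
)
from korders.io import graph_to_dot

universe = PairUniverse(("a", "b", "c"))
orders = tuple(r for r in all_relations(universe) if r.is_transitive())
structure = PreferenceStructure(orders)

g = structure_graph(structure)
print(f"{g.number_of_nodes()} states, {g.number_of_edges()} neighbor edges")
print("degrees:", sorted(d for _, d in g.degree()),
      "-> every order has exactly two one-flip neighbors (the 6-cycle)")
print()
print(graph_to_dot(g))
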