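"""Enumerate the reachable N-glycan reaction network.

Closes the three entry glycans (Man9, Man8, GlcMan9) under the nine-enzyme
rule table and reports the size and shape of the resulting directed acyclic
graph — the combinatorial explosion and sialylated convergence points that
make glycan profiles heterogeneous.
"""

import networkx as nx

from golgisim import enumerate_network
from golgisim.glycans import GlycanState, classify

graph = enumerate_network()
print(f"network: {graph.number_of_nodes()} glycan structures, {graph.number_of_edges()} reactions")
print(f"acyclic: {nx.is_directed_acyclic_graph(graph)} (every event advances maturation)")

leaves = [n for n in graph.nodes if graph.out_degree(n) == 0]
print(f"terminal structures (fully capped or untrimmable): {len(leaves)}")
for code in sorted(leaves)[:5]:
    state = GlycanState.from_code(code)
    cls = classify(state)
    print(f"  {code}  {cls.category}, {cls.antennarity} antennae, {cls.sialylation} NeuAc")

by_comp: dict[str, int] = {}
for _n, data in graph.nodes(data=True):
    by_comp[data["composition"]] = by_comp.get(data["composition"], 0) + 1
isomers = sum(1 for v in by_comp.values() if v > 1)
print(
    f"compositions with structural isomers: {isomers} of {len(by_comp)} "
    "(why composition strings alone cannot identify a structure)"
)
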