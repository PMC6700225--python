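"""Exhaustive enumeration of the reachable reaction network.

Starting from the entry glycans, breadth-first closure under the rule table
yields a finite directed acyclic graph: every enzymatic event strictly
increases the glycan's progress coordinate (trims done + antenna steps +
fucose), so no cycles can occur.  The graph is small enough (a few hundred
states for the canonical table) that it doubles as the state space of an
exact continuous-time Markov chain used to validate the stochastic
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .glycans import ENTRY_GLYCANS, GlycanState, composition
from .rules import EnzymeRule, rule_table


def enumerate_network(
    entry: list[GlycanState] | None = None,
    rules: list[EnzymeRule] | None = None,
) -> nx.DiGraph:
    """Breadth-first closure of the state space under the rule table.

    Nodes are canonical state codes (with ``composition`` attributes); each
    edge carries the acting ``enzyme`` and the number of equivalent sites
    mapping substrate to that product (``multiplicity``, 1 for this rule
    set since distinct sites give distinct products).
    """
    if entry is None:
        entry = list(ENTRY_GLYCANS.values())
    if rules is None:
        rules = rule_table()
    graph = nx.DiGraph()
    frontier = list(entry)
    for s in frontier:
        graph.add_node(s.code(), composition=composition(s))
    while frontier:
        state = frontier.pop()
        code = state.code()
        for rule in rules:
            for product in rule.products(state):
                pcode = product.code()
                if pcode not in graph:
                    graph.add_node(pcode, composition=composition(product))
                    frontier.append(product)
                if graph.has_edge(code, pcode):
                    graph[code][pcode]["multiplicity"] += 1
                else:
                    graph.add_edge(code, pcode, enzyme=rule.enzyme, multiplicity=1)
    return graph


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat, index-based view of the reaction graph for fast simulation.

    ``out_edges[i]`` lists ``(enzyme_index, product_index)`` pairs for state
    ``i``; repeated pairs encode site multiplicity (absent for the canonical
    table).  Enzyme indices refer to ``enzymes``.
    """

    states: tuple[GlycanState, ...]
    codes: tuple[str, ...]
    index: dict
    enzymes: tuple[str, ...]
    out_edges: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_states(self) -> int:
        return len(self.states)


_COMPILED_CACHE: dict[tuple, CompiledNetwork] = {}


def compile_network(
    entry: list[GlycanState] | None = None,
    rules: list[EnzymeRule] | None = None,
) -> CompiledNetwork:
    if entry is None:
        entry = list(ENTRY_GLYCANS.values())
    if rules is None:
        rules = rule_table()
    key = (tuple(sorted(s.code() for s in entry)), id(rules))
    cached = _COMPILED_CACHE.get(key)
    if cached is not None:
        return cached

    graph = enumerate_network(entry, rules)
    codes = tuple(sorted(graph.nodes))
    index = {c: i for i, c in enumerate(codes)}
    states = tuple(GlycanState.from_code(c) for c in codes)
    enzymes = tuple(r.enzyme for r in rules)
    enzyme_index = {e: i for i, e in enumerate(enzymes)}
    out_edges = []
    for i, state in enumerate(states):
        edges = []
        for rule in rules:
            ei = enzyme_index[rule.enzyme]
            for product in rule.products(state):
                edges.append((ei, index[product.code()]))
        out_edges.append(tuple(edges))
    net = CompiledNetwork(
        states=states,
        codes=codes,
        index=index,
        enzymes=enzymes,
        out_edges=tuple(out_edges),
    )
    _COMPILED_CACHE[key] = net
    return net


def write_edge_list(graph: nx.DiGraph, path) -> None:
    """Export the network as a TSV edge list (substrate, product, enzyme)."""
    with open(path, "w") as fh:
        fh.write("substrate_code\tproduct_code\tenzyme\tmultiplicity\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['enzyme']}\t{data['multiplicity']}\n")


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)
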