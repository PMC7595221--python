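"""Dense-module detection: an MCODE reimplementation.

Molecular Complex Detection (MCODE) scores each vertex by its core-clustering
coefficient — the order of the highest k-core of its closed neighbourhood
times that core's density — then greedily grows modules outward from the
highest-weighted unvisited seed, admitting neighbours whose weight exceeds
seed_weight * (1 - VWP).  Post-processing can "haircut" singly-connected
vertices (2-core of the module).  A module's score is its density times its
size; density = 2E / (V(V-1)) for simple graphs.  Modules are node-disjoint.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx


@dataclasses.dataclass
class MCODEParams:
    """Canonical MCODE defaults; the reporting cutoff is applied after search."""

    vwp: float = 0.2  # vertex weight percentage
    degree_cutoff: int = 2
    kcore_threshold: int = 2
    haircut: bool = True
    fluff: bool = False
    max_depth: int = 100
    score_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.vwp < 1:
            raise ValueError("vwp must be in [0, 1)")
        if self.degree_cutoff < 0 or self.kcore_threshold < 0 or self.max_depth < 0:
            raise ValueError("cutoffs must be non-negative")
        if self.fluff:
            raise NotImplementedError("fluff post-processing is not supported")


@dataclasses.dataclass
class Module:
    nodes: tuple[str, ...]
    score: float
    seed: str
    density: float

    @property
    def size(self) -> int:
        return len(self.nodes)


def graph_density(g: nx.Graph) -> float:
    v = g.number_of_nodes()
    if v < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (v * (v - 1))


def neighbourhood_subgraph(net: nx.Graph, ids: Iterable[str]) -> nx.Graph:
    """Subgraph on the ids plus their direct neighbours, then the LCC."""
    ids = set(ids)
    present = ids & set(net.nodes)
    if not present:
        raise ValueError("none of the requested ids are in the network")
    expanded = set(present)
    for v in present:
        expanded.update(net.neighbors(v))
    sub = net.subgraph(expanded)
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    lcc = net.subgraph(comps[0]).copy()
    lcc.graph["n_query"] = len(ids)
    lcc.graph["n_absent"] = len(ids - set(net.nodes))
    lcc.graph["n_neighbours"] = len(expanded - present)
    return lcc


def vertex_weights(net: nx.Graph, degree_cutoff: int = 0) -> dict[str, float]:
    """Core-clustering coefficient per vertex.

    weight(v) = k_max * density of the highest k-core of v's closed
    neighbourhood, where k_max is that core's order.  Isolated vertices (and
    vertices below the degree cutoff) get weight 0.
    """
    weights: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) == 0 or net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = net.subgraph(set(net.neighbors(v)) | {v})
        core_numbers = nx.core_number(closed)
        k_max = max(core_numbers.values())
        core = closed.subgraph([u for u, c in core_numbers.items() if c >= k_max])
        weights[v] = k_max * graph_density(core)
    return weights


def _haircut(nodes: set[str], net: nx.Graph) -> set[str]:
    """Iteratively strip module vertices with fewer than 2 in-module edges."""
    sub = net.subgraph(nodes).copy()
    while True:
        strip = [v for v in sub.nodes if sub.degree(v) < 2]
        if not strip:
            return set(sub.nodes)
        sub.remove_nodes_from(strip)
        if sub.number_of_nodes() == 0:
            return set()


def find_modules(net: nx.Graph, params: MCODEParams | None = None) -> list[Module]:
    """Greedy seed-expansion MCODE module search; modules sorted by score desc."""
    params = params or MCODEParams()
    if net.number_of_nodes() == 0:
        return []
    weights = vertex_weights(net, params.degree_cutoff)
    order = sorted(net.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    modules: list[Module] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.vwp)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            u, depth = frontier.pop(0)
            if depth >= params.max_depth:
                continue
            for w in net.neighbors(u):
                if w in visited or w in members:
                    continue
                if weights[w] > threshold:
                    members.add(w)
                    frontier.append((w, depth + 1))
        visited |= members
        if params.haircut:
            members = _haircut(members, net)
        if not members:
            continue
        sub = net.subgraph(members)
        if members and max(nx.core_number(sub).values(), default=0) < params.kcore_threshold:
            continue
        density = graph_density(sub)
        modules.append(Module(tuple(sorted(members)), density * len(members), seed, density))
    modules.sort(key=lambda mod: (-mod.score, mod.nodes))
    if params.score_cutoff is not None:
        modules = [mod for mod in modules if mod.score > params.score_cutoff]
    return modules


def module_query_fraction(mod: Module, query: Iterable[str]) -> float:
    """Fraction of module nodes that belong to the query set."""
    if mod.size == 0:
        raise ValueError("empty module")
    query = set(query)
    return len(set(mod.nodes) & query) / mod.size


def modules_table(modules: Sequence[Module], query: Iterable[str] | None = None):
    """Summary table: id, score, size, fraction-in-query, node list."""
    import pandas as pd

    query = set(query or ())
    rows = []
    for i, mod in enumerate(modules, start=1):
        frac = module_query_fraction(mod, query) if query else float("nan")
        rows.append((i, mod.score, mod.size, frac, ";".join(mod.nodes)))
    return pd.DataFrame(
        rows, columns=["module_id", "score", "size", "query_fraction", "nodes"]
    ).set_index("module_id")
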