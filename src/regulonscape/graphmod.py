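"""MCODE dense-module detection on (weighted) interaction graphs.

MCODE is a vertex-weighting clustering algorithm: each vertex is scored by
the density of the highest k-core of its closed neighborhood times that
core's k (the core-clustering coefficient); complexes grow outward from
locally dense seed vertices, including neighbours whose weight stays within
``node_score_cutoff`` of the seed's; grown complexes must contain a
``k_core``-core and are scored density x size.  Edge weights (STRING-style
combined scores) are used only for optional input filtering — the algorithm
itself is purely topological, as in the original formulation.

Default parameters: degree cutoff 2, node score cutoff 0.2, K-core 2,
module score cutoff 3.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    score_cutoff: float = 3.0
    fluff: bool = False
    haircut: bool = False

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.k_core < 0:
            raise ValueError("degree_cutoff and k_core must be non-negative")
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValueError("node_score_cutoff must lie in [0, 1]")


@dataclass
class GraphModule:
    members: list[str]
    seed: str
    score: float


def graph_from_edges(edges: pd.DataFrame, min_score: float | None = None) -> nx.Graph:
    """Build a simple undirected graph from a node_a/node_b/combined_score
    edge list, optionally dropping edges below ``min_score``."""
    G = nx.Graph()
    for a, b, w in edges[["node_a", "node_b", "combined_score"]].itertuples(index=False):
        if a == b:
            continue
        if min_score is not None and w < min_score:
            continue
        G.add_edge(str(a), str(b), combined_score=float(w))
    return G


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph with all degrees >= k (iterative peeling)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if graph.number_of_nodes() == 0:
        return graph.copy()
    return nx.k_core(graph, k)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """Core-clustering weight per vertex: k_max x density of the highest
    k-core of the closed neighborhood N[v]; 0 below the degree cutoff."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        H = graph.subgraph([v, *graph.neighbors(v)])
        core_nums = nx.core_number(H)
        k_max = max(core_nums.values())
        core = H.subgraph([u for u, c in core_nums.items() if c >= k_max])
        weights[v] = k_max * _density(core)
    return weights


def module_score(graph: nx.Graph, members) -> float:
    """MCODE module score: density x number of vertices."""
    H = graph.subgraph(members)
    return _density(H) * H.number_of_nodes()


def find_complexes(
    graph: nx.Graph,
    params: McodeParams | None = None,
    include_subthreshold: bool = False,
) -> list[GraphModule]:
    """MCODE complex prediction.

    Seeds are taken in descending weight order over unvisited vertices;
    growth adds, by outward traversal, unvisited neighbours with weight >=
    seed_weight * (1 - node_score_cutoff); included vertices are marked
    visited, so returned modules are vertex-disjoint.  Complexes lacking a
    ``k_core``-core are dropped.  By default only modules with score >=
    ``score_cutoff`` are returned (the reporting filter); pass
    ``include_subthreshold=True`` for the full list.
    """
    params = params or McodeParams()
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weights = vertex_weights(graph, params.degree_cutoff)
    visited: set[str] = set()
    modules: list[GraphModule] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in graph.neighbors(v):
                    if u in members or u in visited:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        H = graph.subgraph(members)
        if params.haircut:
            H = _haircut(H)
            members = set(H.nodes)
        if not members or k_core(H, params.k_core).number_of_nodes() == 0:
            visited |= members
            continue
        if params.fluff:
            members = _fluff(graph, members, weights, threshold)
            H = graph.subgraph(members)
        visited |= members
        modules.append(
            GraphModule(members=sorted(members), seed=seed, score=module_score(graph, members))
        )
    modules.sort(key=lambda m: (-m.score, -len(m.members), m.seed))
    if include_subthreshold:
        return modules
    return [m for m in modules if m.score >= params.score_cutoff]


def _haircut(H: nx.Graph) -> nx.Graph:
    """Remove singly connected vertices from a complex."""
    H = nx.Graph(H)
    changed = True
    while changed:
        leaves = [v for v in H.nodes if H.degree(v) < 2]
        changed = bool(leaves)
        H.remove_nodes_from(leaves)
    return H


def _fluff(graph: nx.Graph, members: set, weights: dict, threshold: float) -> set:
    """Add boundary neighbours whose neighborhood weight clears the same
    threshold (one ring only)."""
    extra = {
        u
        for v in members
        for u in graph.neighbors(v)
        if u not in members and weights[u] >= threshold
    }
    return members | extra
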