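"""MCODE dense-module detection on a protein-protein interaction graph.

Vertex weighting, greedy seeded expansion, haircut post-processing and a
final k-core module filter.  Members of the surviving modules are the
pipeline's hub genes.  Parameter defaults follow the renal-injury screening
convention (seed degree cutoff 3, module 4-core filter); the classical
MCODE defaults (2, 2) are a configuration change away.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx

from .dataio import DataError


@dataclass
class Module:
    members: frozenset
    seed: str
    score: float  # density x size of the module subgraph


@dataclass
class ModuleSet:
    modules: list[Module]
    vertex_weights: dict[str, float]

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)


def _check_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise DataError("PPI graph must be undirected and simple")
    if any(u == v for u, v in graph.edges()):
        raise DataError("PPI graph must have no self-loops")


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph in which every vertex has >= k neighbours inside it.

    Computed by iterative deletion of under-degree vertices, which converges
    to the unique maximal such subgraph (possibly empty).
    """
    if k < 0:
        raise DataError("k must be non-negative")
    _check_simple(graph)
    sub = graph.copy()
    while True:
        weak = [v for v, d in sub.degree() if d < k]
        if not weak:
            return sub
        sub.remove_nodes_from(weak)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def vertex_weight(graph: nx.Graph, v) -> float:
    """MCODE core-clustering weight: k x density of the highest k-core of the
    closed neighbourhood of ``v``; 0 for an isolated vertex."""
    if v not in graph:
        raise DataError(f"vertex {v!r} not in graph")
    closed = set(graph[v]) | {v}
    h = graph.subgraph(closed)
    best_k, best_core = 0, None
    core = h.copy()
    for k in range(1, len(closed) + 1):
        core = k_core(core, k)  # k-cores nest, so peel incrementally
        if core.number_of_nodes() == 0:
            break
        best_k, best_core = k, core.copy()
    if best_core is None:
        return 0.0
    return best_k * _density(best_core)


def _haircut(graph: nx.Graph, members: set) -> set:
    """Iteratively remove vertices with within-module degree < 2."""
    members = set(members)
    while True:
        sub = graph.subgraph(members)
        weak = {v for v, d in sub.degree() if d < 2}
        if not weak or weak == members:
            return members - weak if weak == members else members
        members -= weak


def find_modules(
    graph: nx.Graph,
    degree_cutoff: int = 3,
    kcore_filter: int = 4,
    vwp: float = 0.2,
    haircut: bool = True,
) -> ModuleSet:
    """Greedy MCODE module search.

    Seeds are taken in order of decreasing vertex weight (ties broken by
    symbol) among vertices of degree >= ``degree_cutoff``.  Expansion admits
    unused neighbours whose weight is >= seed weight x (1 - ``vwp``),
    breadth-first; every vertex joins at most one module.  After the optional
    haircut, modules lacking a non-empty ``kcore_filter``-core are discarded.
    Surviving modules are sorted by score = density x size, descending.
    """
    if not 0 <= vwp <= 1:
        raise DataError("vwp must lie in [0, 1]")
    if degree_cutoff < 0 or kcore_filter < 0:
        raise DataError("cutoffs must be non-negative")
    _check_simple(graph)

    weights = {v: vertex_weight(graph, v) for v in graph}
    seeds = sorted(
        (v for v in graph if graph.degree(v) >= degree_cutoff),
        key=lambda v: (-weights[v], str(v)),
    )

    used: set = set()
    modules: list[Module] = []
    for seed in seeds:
        if seed in used:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        queue = deque([seed])
        while queue:
            v = queue.popleft()
            for u in sorted(graph[v], key=str):
                if u in members or u in used:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    queue.append(u)
        used |= members
        if haircut:
            members = _haircut(graph, members)
        if not members:
            continue
        # haircut can sever a cut vertex; keep one connected piece (the seed's,
        # else the largest with lexicographic tie-break) so modules stay connected
        components = sorted(nx.connected_components(graph.subgraph(members)),
                            key=lambda c: (-len(c), sorted(str(v) for v in c)))
        members = next((c for c in components if seed in c), components[0])
        sub = graph.subgraph(members)
        if kcore_filter > 0 and k_core(sub, kcore_filter).number_of_nodes() == 0:
            continue
        modules.append(
            Module(members=frozenset(members), seed=seed, score=_density(sub) * len(members))
        )

    modules.sort(key=lambda m: (-m.score, sorted(str(v) for v in m.members)))
    return ModuleSet(modules=modules, vertex_weights=weights)


def hub_genes(modules: ModuleSet) -> list:
    """Union of module members, ordered by (module score, vertex weight) desc."""
    seen = set()
    ordered = []
    for mod in modules.modules:
        for v in sorted(mod.members, key=lambda u: (-modules.vertex_weights.get(u, 0.0), str(u))):
            if v not in seen:
                seen.add(v)
                ordered.append(v)
    return ordered
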