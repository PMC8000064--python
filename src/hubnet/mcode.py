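"""Molecular-complex (MCODE-style) dense-module detection.

Three stages, pinned to the Cytoscape-default variant of the algorithm:

1. *Vertex weighting* — for each node with degree >= the degree cutoff, take
   the closed neighborhood, find its highest k-core, and weight the node by
   k_max times the density of that core.  Nodes below the cutoff weigh 0.
2. *Module growth* — seed at unvisited nodes in descending weight and expand
   breadth-first, admitting a neighbor when its weight is at least
   (1 - node_score_cutoff) times the seed weight, up to a maximum depth.
   Nodes belong to at most one module (visited-node rule).
3. *Post-processing* — discard candidates lacking a 2-core, shave
   degree-<2 nodes off ("haircut"), and recompute density and score.

A module's score is its induced-subgraph density times its node count;
downstream filtering keeps modules with score strictly above a minimum
(study value: 5).  Seed tie-breaks and neighbor iteration are lexicographic
by symbol so runs are reproducible under any node ordering.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

__all__ = [
    "NetworkModule",
    "score_vertices",
    "grow_modules",
    "postprocess",
    "filter_modules",
    "detect_modules",
]


@dataclass(frozen=True)
class NetworkModule:
    """A dense subgraph: node set, seed, induced density, and density x size score."""

    nodes: frozenset[str]
    seed_node: str
    density: float
    score: float

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a module needs at least 2 nodes")


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def score_vertices(net: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """k-core-based vertex weights over closed neighborhoods."""
    weights: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = list(net.neighbors(v)) + [v]
        sub = net.subgraph(closed)
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        core_nodes = [u for u, k in core_numbers.items() if k >= k_max]
        core = sub.subgraph(core_nodes)
        weights[v] = float(k_max) * _density(core)
    return weights


def grow_modules(
    net: nx.Graph,
    weights: Mapping[str, float],
    node_score_cutoff: float = 0.2,
    max_depth: int = 100,
) -> list[tuple[str, set[str]]]:
    """Greedy breadth-first module growth from high-weight seeds.

    Returns (seed, node set) candidates in seeding order.  A neighbor is
    admitted iff its weight is >= (1 - node_score_cutoff) times the seed's
    weight and it is not yet assigned to a module.
    """
    visited: set[str] = set()
    candidates: list[tuple[str, set[str]]] = []
    seeds = sorted(net.nodes, key=lambda v: (-weights.get(v, 0.0), v))
    for seed in seeds:
        if seed in visited or weights.get(seed, 0.0) <= 0.0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        module = {seed}
        visited.add(seed)
        queue = deque([(seed, 0)])
        while queue:
            v, depth = queue.popleft()
            if depth >= max_depth:
                continue
            for u in sorted(net.neighbors(v)):
                if u in visited or u in module:
                    continue
                if weights.get(u, 0.0) >= threshold:
                    module.add(u)
                    visited.add(u)
                    queue.append((u, depth + 1))
        candidates.append((seed, module))
    return candidates


def postprocess(
    candidates: Sequence[tuple[str, set[str]]],
    net: nx.Graph,
    k_core: int = 2,
    haircut: bool = True,
) -> list[NetworkModule]:
    """Apply the k-core filter and haircut, then rescore.

    Candidates whose induced subgraph has no ``k_core``-core are discarded;
    the haircut removes nodes with within-module degree < 2 (single pass);
    modules shrinking below 2 nodes are dropped.  Output sorted by score
    descending, ties by node set.
    """
    modules: list[NetworkModule] = []
    for seed, nodes in candidates:
        sub = net.subgraph(nodes)
        if sub.number_of_nodes() < 2:
            continue
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            continue
        if haircut:
            keep = [v for v in sub.nodes if sub.degree(v) >= 2]
            sub = net.subgraph(keep)
        if sub.number_of_nodes() < 2:
            continue
        density = _density(sub)
        modules.append(
            NetworkModule(
                nodes=frozenset(sub.nodes),
                seed_node=seed,
                density=density,
                score=density * sub.number_of_nodes(),
            )
        )
    modules.sort(key=lambda m: (-m.score, tuple(sorted(m.nodes))))
    return modules


def filter_modules(
    modules: Sequence[NetworkModule], min_score: float = 5.0
) -> list[NetworkModule]:
    """Keep modules with score strictly greater than ``min_score``."""
    return [m for m in modules if m.score > min_score]


def detect_modules(
    net: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    min_score: float | None = None,
) -> list[NetworkModule]:
    """Full vertex-weighting -> growth -> post-processing chain.

    ``min_score`` of None returns all post-processed modules; otherwise the
    strict score filter is applied.
    """
    weights = score_vertices(net, degree_cutoff=degree_cutoff)
    candidates = grow_modules(
        net, weights, node_score_cutoff=node_score_cutoff, max_depth=max_depth
    )
    modules = postprocess(candidates, net, k_core=k_core, haircut=haircut)
    if min_score is not None:
        modules = filter_modules(modules, min_score=min_score)
    return modules
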