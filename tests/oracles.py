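"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — plain BFS, all-pairs shortest-path
counting, closed-form combinatorics, hand product-limit arithmetic — and
shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# graph centralities (edge lists of hashable node pairs)


def adjacency(edges, nodes=None):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    for n in nodes or ():
        adj.setdefault(n, set())
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def brute_degree(adj):
    return {v: len(nbrs) for v, nbrs in adj.items()}


def brute_closeness(adj):
    """(n_c - 1) / sum of distances within the node's component."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def brute_mean_neighbor_degree(adj):
    deg = brute_degree(adj)
    return {
        v: (sum(deg[u] for u in nbrs) / len(nbrs) if nbrs else 0.0)
        for v, nbrs in adj.items()
    }


def brute_betweenness(adj, normalized=True):
    """All-pairs shortest-path counting: sigma(s,v)*sigma(v,t)/sigma(s,t)."""
    nodes = sorted(adj)
    # per-source shortest-path counts
    sigma = {}
    dist = {}
    for s in nodes:
        d = bfs_distances(adj, s)
        counts = {s: 1}
        for v in sorted(d, key=d.get):
            if v == s:
                continue
            counts[v] = sum(
                counts[u] for u in adj[v] if u in d and d[u] == d[v] - 1
            )
        sigma[s] = counts
        dist[s] = d
    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        for v in nodes:
            if v in (s, t) or v not in dist[s] or t not in dist[v]:
                continue
            if dist[s][v] + dist[v][t] == d_st:
                bet[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    if normalized:
        n = len(nodes)
        scale = (n - 1) * (n - 2) / 2
        if scale > 0:
            bet = {v: b / scale for v, b in bet.items()}
    return bet


def brute_kcore_max(edges, nodes):
    """Highest k with a non-empty k-core, plus that core's node set, by peeling."""
    adj = adjacency(edges, nodes)
    best_k, best_nodes = 0, set(adj)
    k = 1
    while True:
        cur = {v: set(n) for v, n in adj.items()}
        changed = True
        while changed:
            changed = False
            for v in list(cur):
                if len(cur[v]) < k:
                    for u in cur[v]:
                        cur[u].discard(v)
                    del cur[v]
                    changed = True
        if not cur:
            return best_k, best_nodes
        best_k, best_nodes = k, set(cur)
        k += 1


def subgraph_density(edges, nodes):
    nodes = set(nodes)
    e = sum(1 for a, b in edges if a in nodes and b in nodes)
    n = len(nodes)
    return 2 * e / (n * (n - 1)) if n > 1 else 0.0


# ---------------------------------------------------------------------------
# hypergeometric

def hypergeom_tail_comb(k, n, K, N):
    """Upper tail P(X >= k) by the closed-form combinatorial sum."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    ) / denom


def hypergeom_tail_enumerate(k, n, K, N):
    """Upper tail by full enumeration of all C(N, n) draws (tiny N only)."""
    hits = 0
    total = 0
    successes = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# survival

def km_by_hand(times, events):
    """Product-limit estimate as a list of (event time, survival)."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, float)[order]
    events = np.asarray(events, int)[order]
    at_risk = len(times)
    s = 1.0
    out = []
    for t in np.unique(times):
        d = int(events[times == t].sum())
        n_t = int((times >= t).sum())
        if d > 0:
            s *= 1 - d / n_t
            out.append((float(t), s))
    return out


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Mantel-Haenszel chi-square over the 2x2 table at each event time."""
    times = np.concatenate([times_a, times_b]).astype(float)
    events = np.concatenate([events_a, events_b]).astype(int)
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return chi2
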