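"""Confidence-filtered interaction network and the hybrid centrality hub score.

The hub score of a node is the plain sum of four terms:

    HCM(v) = degree(v) + closeness(v) + betweenness(v) + mean neighbor degree(v)

The four terms are of incommensurate scale, so the summation is performed
under a declared normalization mode that is stamped into outputs:

* ``default`` — raw degree + normalized closeness in [0,1] + normalized
  betweenness in [0,1] + raw mean neighbor degree.  Degree-scale terms
  dominate, which is the only reading under which an absolute hub threshold
  such as 12 is meaningful.
* ``all_raw`` — raw degree + closeness as (n_c-1)/sum of distances +
  unnormalized betweenness (pair counts) + raw mean neighbor degree.
* ``all_normalized`` — degree/(n-1) + normalized closeness + normalized
  betweenness + mean neighbor degree/(n-1).

Shortest paths are unweighted (edge confidence is a filter, not a distance),
matching standard Cytoscape-ecosystem practice for these centralities.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMALIZATION_MODES = ("default", "all_raw", "all_normalized")

__all__ = [
    "build_network",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "mean_neighbor_degree",
    "hybrid_centrality",
    "compute_node_metrics",
    "select_hubs",
    "NORMALIZATION_MODES",
]


def build_network(
    edges: pd.DataFrame,
    min_confidence: float = 0.4,
    restrict_to: Iterable[str] | None = None,
) -> nx.Graph:
    """Simple undirected graph from weighted edge records.

    Keeps edges with confidence strictly greater than ``min_confidence``
    whose both endpoints lie in ``restrict_to`` (when given, typically the
    DEG set).  Duplicate rows and reversed duplicates collapse to one edge
    (highest confidence wins).
    """
    g = nx.Graph()
    allowed = None if restrict_to is None else {str(x) for x in restrict_to}
    for a, b, conf in edges[["node_a", "node_b", "confidence"]].itertuples(index=False):
        a, b = str(a), str(b)
        if a == b or float(conf) <= min_confidence:
            continue
        if allowed is not None and (a not in allowed or b not in allowed):
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], float(conf))
        else:
            g.add_edge(a, b, confidence=float(conf))
    if allowed is not None:
        # retain isolated query genes so they appear (flagged) in metrics
        g.add_nodes_from(sorted(allowed - set(g.nodes)))
    if g.number_of_edges() == 0:
        logger.warning("build_network: empty network after filtering")
    return g


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw incident-edge counts."""
    return {n: int(d) for n, d in net.degree()}


def closeness_centrality(net: nx.Graph, wf_improved: bool = False) -> dict[str, float]:
    """Per-component closeness: (n_c - 1) / sum of distances to the component.

    ``wf_improved`` switches on the Wasserman-Faust scaling by component
    size relative to the full graph.  Isolated nodes get 0.
    """
    return {n: float(c) for n, c in nx.closeness_centrality(net, wf_improved=wf_improved).items()}


def betweenness_centrality(net: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Brandes betweenness; normalized by (n-1)(n-2)/2 when requested."""
    if net.number_of_nodes() < 3:
        return {n: 0.0 for n in net.nodes}
    return {
        n: float(b)
        for n, b in nx.betweenness_centrality(net, normalized=normalized).items()
    }


def mean_neighbor_degree(net: nx.Graph) -> dict[str, float]:
    """Arithmetic mean of the neighbors' raw degrees; isolated nodes get 0."""
    out: dict[str, float] = {}
    for v in net.nodes:
        nbrs = list(net.neighbors(v))
        if not nbrs:
            out[v] = 0.0
        else:
            out[v] = float(np.mean([net.degree(u) for u in nbrs]))
    return out


def hybrid_centrality(
    degree: Mapping[str, float],
    closeness: Mapping[str, float],
    betweenness: Mapping[str, float],
    neighbor_degree: Mapping[str, float],
) -> dict[str, float]:
    """Plain sum of the four centrality components, per node."""
    nodes = set(degree)
    for comp, name in ((closeness, "closeness"), (betweenness, "betweenness"),
                       (neighbor_degree, "mean_neighbor_degree")):
        if set(comp) != nodes:
            raise ValueError(f"component {name} does not cover all nodes")
    return {
        v: float(degree[v]) + float(closeness[v]) + float(betweenness[v])
        + float(neighbor_degree[v])
        for v in nodes
    }


def compute_node_metrics(net: nx.Graph, mode: str = "default") -> pd.DataFrame:
    """Per-node centralities and HCM under a declared normalization mode.

    Columns: gene, degree, closeness, betweenness, mean_neighbor_degree,
    hcm, isolated.  The mode is recorded in ``DataFrame.attrs['mode']``.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    deg = degree_centrality(net)
    mnd = mean_neighbor_degree(net)
    n = net.number_of_nodes()
    if mode == "all_raw":
        clo = closeness_centrality(net)
        bet = betweenness_centrality(net, normalized=False)
        deg_term = {v: float(d) for v, d in deg.items()}
        mnd_term = mnd
    elif mode == "all_normalized":
        clo = closeness_centrality(net)
        bet = betweenness_centrality(net, normalized=True)
        scale = (n - 1) if n > 1 else 1
        deg_term = {v: d / scale for v, d in deg.items()}
        mnd_term = {v: m / scale for v, m in mnd.items()}
    else:
        clo = closeness_centrality(net)
        bet = betweenness_centrality(net, normalized=True)
        deg_term = {v: float(d) for v, d in deg.items()}
        mnd_term = mnd
    hcm = hybrid_centrality(deg_term, clo, bet, mnd_term)
    rows = [
        {
            "gene": v,
            "degree": deg[v],
            "closeness": clo[v],
            "betweenness": bet[v],
            "mean_neighbor_degree": mnd[v],
            "hcm": hcm[v],
            "isolated": deg[v] == 0,
        }
        for v in sorted(net.nodes)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "degree", "closeness", "betweenness",
            "mean_neighbor_degree", "hcm", "isolated",
        ],
    )
    df.attrs["mode"] = mode
    return df


def select_hubs(
    metrics: pd.DataFrame,
    threshold: float = 12.0,
    deg_records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Nodes with HCM strictly above the threshold, split by regulation.

    Direction comes from DEG records (positive logFC = upregulated); genes
    without a record are retained with direction ``unknown`` and logged.
    Output sorted by HCM descending, ties broken by symbol.
    """
    hubs = metrics[metrics["hcm"] > threshold].copy()
    dirs: dict[str, str] = {}
    if deg_records is not None:
        dirs = dict(zip(deg_records["gene"], deg_records["direction"]))
    direction = [dirs.get(g, "unknown") for g in hubs["gene"]]
    n_unknown = sum(d == "unknown" for d in direction)
    if n_unknown and deg_records is not None:
        logger.info("select_hubs: %d hubs lack a DEG record", n_unknown)
    hubs["direction"] = direction
    hubs = hubs.sort_values(
        ["hcm", "gene"], ascending=[False, True], ignore_index=True
    )
    hubs.attrs["mode"] = metrics.attrs.get("mode", "default")
    return hubs
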