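"""Hypergeometric over-representation analysis of gene lists.

Given a query of n genes from a universe of N genes, K of which belong to a
gene set, the probability of observing at least k annotated genes in the
query is the upper hypergeometric tail P(X >= k) — equivalently a one-sided
Fisher exact test.  An EASE-style conservative variant (score the overlap as
k-1) is available behind a flag.

The default universe is the union of all sets plus the query genes; an
explicit universe can be supplied via the collection.  Sets are kept when
p < 0.05 (strict) and the overlap count is at least 2 by default; the
printed result tables this mirrors contain count-2 rows, so the minimum
count is inclusive.  No multiple-testing correction is applied by default
(mirroring raw-p reporting); Benjamini-Hochberg is available.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["hypergeometric_tail", "enrich", "tally_directions"]


def hypergeometric_tail(k: int, n: int, K: int, N: int, ease: bool = False) -> float:
    """Upper-tail P(X >= k) for a hypergeometric draw of n from N with K successes."""
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    kk = max(k - 1, 0) if ease else k
    return float(stats.hypergeom.sf(kk - 1, N, K, n))


def enrich(
    query: Sequence[str],
    collection: GeneSetCollection,
    min_count: int = 2,
    p_threshold: float = 0.05,
    adjust: str = "none",
    ease: bool = False,
) -> pd.DataFrame:
    """Over-representation of every set in the collection against a query.

    Returns sets with p strictly below ``p_threshold`` and overlap count of
    at least ``min_count``, sorted by p ascending (ties by set id).  Columns:
    set_id, description, overlap_count, overlap_genes, n_set, p_value and
    (when ``adjust='bh'``) adjusted_p computed over all tested sets before
    filtering.
    """
    if adjust not in {"none", "bh"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    query_set = {str(g) for g in query}
    if not query_set:
        raise ValueError("empty query")
    universe = set(collection.universe) | query_set
    usable_query = query_set & set(collection.universe)
    if not usable_query and collection.universe:
        raise ValueError(
            "query is disjoint from the collection universe (symbol-space mismatch)"
        )
    N = len(universe)
    n = len(query_set)
    rows = []
    for set_id in sorted(collection.sets):
        members = collection.sets[set_id] & universe
        K = len(members)
        overlap = sorted(members & query_set)
        k = len(overlap)
        p = hypergeometric_tail(k, n, K, N, ease=ease)
        rows.append(
            {
                "set_id": set_id,
                "description": collection.descriptions.get(set_id, ""),
                "overlap_count": k,
                "overlap_genes": ",".join(overlap),
                "n_set": K,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows)
    if adjust == "bh":
        result["adjusted_p"] = _benjamini_hochberg(result["p_value"].to_numpy())
    keep = (result["p_value"] < p_threshold) & (result["overlap_count"] >= min_count)
    result = result[keep].sort_values(
        ["p_value", "set_id"], ignore_index=True
    )
    result.attrs["universe_size"] = N
    result.attrs["query_size"] = n
    return result


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment; preserves the raw-p ranking and never drops below p."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def tally_directions(
    result: pd.DataFrame, deg_records: pd.DataFrame
) -> pd.DataFrame:
    """Add n_up / n_down / n_unknown tallies per enriched set.

    Directions come from DEG records (columns gene, direction); overlap
    genes without a record count as unknown.  Invariant:
    n_up + n_down + n_unknown = overlap_count.
    """
    dirs = dict(zip(deg_records["gene"], deg_records["direction"]))
    n_up, n_down, n_unknown = [], [], []
    for genes in result["overlap_genes"]:
        members = [g for g in str(genes).split(",") if g] if pd.notna(genes) else []
        ups = sum(dirs.get(g) == "up" for g in members)
        downs = sum(dirs.get(g) == "down" for g in members)
        n_up.append(ups)
        n_down.append(downs)
        n_unknown.append(len(members) - ups - downs)
    return result.assign(n_up=n_up, n_down=n_down, n_unknown=n_unknown)
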