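"""Per-generation differential expression, cross-generation partition, and
functional classification of DEG lists.

A gene is called differentially expressed in a treated-vs-control comparison
when its log2 fold change strictly exceeds 1 in magnitude and its two-sided
p-value is strictly below 0.05 (both thresholds configurable; boundary genes
are excluded).  The cross-generation common set is partitioned into genes up
in every generation, down in every generation, and discordant ("both").

The per-gene statistic is a Welch t-test by default.  A moderated-variance
mode (shrinkage of per-gene variances toward the median variance) is
available as an approximation to empirical-Bayes pipelines; bit
compatibility with them is not claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTROL, TREATED, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "test_differential",
    "call_degs",
    "partition_common",
    "classify_by_annotation",
    "CommonDEGPartition",
    "ClassTally",
]


def _welch(
    treated: np.ndarray, control: np.ndarray, moderate: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t-test per gene (rows).

    Returns (logfc, t, p).  ``moderate`` in [0, 1) shrinks each group's
    per-gene variance toward the median per-gene variance of that group.
    Degenerate rows where both groups have zero variance get t=0, p=1 when
    the means agree (no evidence either way) and t=+/-inf, p=0 otherwise.
    """
    n1, n2 = treated.shape[1], control.shape[1]
    m1, m2 = treated.mean(axis=1), control.mean(axis=1)
    v1, v2 = treated.var(axis=1, ddof=1), control.var(axis=1, ddof=1)
    if moderate:
        v1 = (1 - moderate) * v1 + moderate * np.median(v1)
        v2 = (1 - moderate) * v2 + moderate * np.median(v2)
    logfc = m1 - m2
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    zero = se2 == 0
    if np.any(zero):
        logger.info("zero within-group variance for %d genes", int(zero.sum()))
        with np.errstate(invalid="ignore"):
            t = np.where(zero, np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf), t)
        df = np.where(zero, 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero & (logfc == 0), 1.0, p)
    p = np.where(zero & (logfc != 0), 0.0, p)
    return logfc, t, p


def test_differential(
    matrix: ExpressionMatrix,
    generation: int,
    moderate: float = 0.0,
) -> pd.DataFrame:
    """Treated-vs-control statistics for one xenograft generation.

    Returns a DataFrame with columns gene, logfc (log2, treated minus
    control), t_stat, p_value.  Rows with missing values in either compared
    group are excluded from testing and logged.
    """
    treated_ids = matrix.samples_for(TREATED, generation)
    control_ids = matrix.samples_for(CONTROL)
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise ValueError(
            f"generation {generation}: need >=2 replicates per group "
            f"(got {len(treated_ids)} treated, {len(control_ids)} control)"
        )
    sub = matrix.values[treated_ids + control_ids]
    complete = sub.notna().all(axis=1)
    if not complete.all():
        logger.info(
            "generation %s: excluded %d genes with missing values",
            generation,
            int((~complete).sum()),
        )
    sub = sub.loc[complete]
    logfc, t, p = _welch(
        sub[treated_ids].to_numpy(float), sub[control_ids].to_numpy(float), moderate
    )
    return pd.DataFrame(
        {"gene": sub.index, "logfc": logfc, "t_stat": t, "p_value": p}
    ).reset_index(drop=True)


def call_degs(
    stats_table: pd.DataFrame,
    logfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assign up/down/none calls with strict thresholds.

    ``up`` iff logfc > logfc_threshold and p < p_threshold; ``down`` iff
    logfc < -logfc_threshold and p < p_threshold; otherwise ``none``.  A
    gene with logfc exactly at the threshold is not a DEG.
    """
    logfc = stats_table["logfc"].to_numpy(float)
    p = stats_table["p_value"].to_numpy(float)
    sig = p < p_threshold
    direction = np.where(
        sig & (logfc > logfc_threshold),
        "up",
        np.where(sig & (logfc < -logfc_threshold), "down", "none"),
    )
    return stats_table.assign(direction=direction)


@dataclass
class CommonDEGPartition:
    """Genes differential in every generation, split by direction agreement."""

    up: frozenset[str]
    down: frozenset[str]
    both: frozenset[str]
    per_generation_counts: dict[int, int] = field(default_factory=dict)

    @property
    def common(self) -> frozenset[str]:
        return self.up | self.down | self.both

    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "up": len(self.up),
            "down": len(self.down),
            "both": len(self.both),
        }


def partition_common(deg_tables: Mapping[int, pd.DataFrame]) -> CommonDEGPartition:
    """Partition the intersection of per-generation DEG sets by direction.

    A gene is common iff its direction is not ``none`` in every generation;
    it is assigned up/down when the direction agrees across generations, and
    to the discordant ``both`` category otherwise.  Invariant (asserted):
    up, down, both are pairwise disjoint and exhaust the common set, and the
    result does not depend on generation order.
    """
    if len(deg_tables) < 2:
        raise ValueError("need at least two generations to intersect")
    directions: dict[int, dict[str, str]] = {}
    counts: dict[int, int] = {}
    for gen, table in deg_tables.items():
        called = table[table["direction"] != "none"]
        directions[int(gen)] = dict(zip(called["gene"], called["direction"]))
        counts[int(gen)] = len(called)

    common = set.intersection(*(set(d) for d in directions.values()))
    up, down, both = set(), set(), set()
    for gene in common:
        dirs = {d[gene] for d in directions.values()}
        if dirs == {"up"}:
            up.add(gene)
        elif dirs == {"down"}:
            down.add(gene)
        else:
            both.add(gene)
    part = CommonDEGPartition(
        up=frozenset(up),
        down=frozenset(down),
        both=frozenset(both),
        per_generation_counts=counts,
    )
    assert not (part.up & part.down or part.up & part.both or part.down & part.both)
    assert part.common == frozenset(common)
    return part


@dataclass
class ClassTally:
    """Members of one functional class found in a query, with direction tallies."""

    members: frozenset[str]
    n_up: int
    n_down: int


def classify_by_annotation(
    genes: Sequence[str],
    class_map: GeneSetCollection | Mapping[str, frozenset[str]],
    deg_records: pd.DataFrame | None = None,
) -> dict[str, ClassTally]:
    """Intersect a gene list with functional classes and tally directions.

    ``class_map`` is a GMT-style mapping class -> member symbols (growth
    factors, cytokines, proto-oncogenes, ...).  Direction tallies come from
    ``deg_records`` (columns gene, direction); query genes lacking a
    direction record are counted as members but excluded from the tallies
    (logged).
    """
    if isinstance(class_map, GeneSetCollection):
        class_sets = class_map.sets
    else:
        class_sets = {k: frozenset(v) for k, v in class_map.items()}
    dirs: dict[str, str] = {}
    if deg_records is not None:
        dirs = dict(zip(deg_records["gene"], deg_records["direction"]))
    query = set(str(g) for g in genes)
    out: dict[str, ClassTally] = {}
    for cls, members in class_sets.items():
        hit = frozenset(members & query)
        known = [g for g in hit if g in dirs]
        if len(known) < len(hit) and deg_records is not None:
            logger.info(
                "class %s: %d members lack direction records", cls, len(hit) - len(known)
            )
        out[cls] = ClassTally(
            members=hit,
            n_up=sum(dirs[g] == "up" for g in known),
            n_down=sum(dirs[g] == "down" for g in known),
        )
    return out
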