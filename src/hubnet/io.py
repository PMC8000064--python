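"""Readers and writers for every external representation the pipeline touches.

Dialects
--------
* Expression table: TSV, first column ``gene_id`` (or probe id), remaining
  columns one per sample, log2-intensity values.  Lines starting with ``#``
  are comments; the writer emits ``# scale: log2`` so the scale is declared
  rather than guessed.  Group labels live in a sidecar TSV with columns
  ``sample_id``, ``condition`` (control/treated) and ``generation`` (int).
* Probe annotation: two-column TSV ``probe_id``, ``gene_symbol``; an empty
  symbol marks an unmapped probe.
* Edge list: STRING-export-style TSV with columns ``node_a``, ``node_b``,
  ``combined_score``.  Scores are normalized to [0, 1] on read.
* Gene sets: standard GMT (set id, description, then member symbols).
* Survival table: TSV with ``subject_id``, ``time_months``, ``event`` and
  one column per screened gene.
* Reports: TSV (12 significant digits) or JSON, deterministic column order.

Gene symbols are opaque, case-sensitive tokens throughout; an optional
uppercase-normalization switch exists on the annotation reader (default off)
because silent case folding hides real mismatches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression_table",
    "write_expression_table",
    "read_probe_annotation",
    "collapse_probes",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_survival_table",
    "write_survival_table",
    "write_report",
    "read_report",
]


@dataclass
class ExpressionMatrix:
    """Log2-scale genes x samples expression with per-sample group labels.

    ``values`` is a DataFrame indexed by gene (or probe) id with one column
    per sample; ``groups`` is indexed by sample id with columns ``condition``
    (``control``/``treated``) and ``generation`` (int).
    """

    values: pd.DataFrame
    groups: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene/probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.groups["condition"]) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def generations(self) -> list[int]:
        gens = self.groups.loc[self.groups["condition"] == TREATED, "generation"]
        return sorted(set(int(g) for g in gens))

    def samples_for(self, condition: str, generation: int | None = None) -> list[str]:
        """Sample ids for a condition; controls ignore ``generation`` when shared."""
        mask = self.groups["condition"] == condition
        if generation is not None and condition == TREATED:
            mask &= self.groups["generation"].astype(int) == int(generation)
        return [s for s in self.groups.index[mask] if s in self.values.columns]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe used for enrichment.

    Sets are intersected with the universe at construction when an explicit
    universe is given; by default the universe is the union of all sets.
    """

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"gene set {set_id!r} is empty")
            if any(not str(m).strip() for m in members):
                raise ValueError(f"gene set {set_id!r} has an empty member token")
        if not self.universe:
            u: set[str] = set()
            for members in self.sets.values():
                u |= members
            self.universe = frozenset(u)
        else:
            self.universe = frozenset(self.universe)
            self.sets = {
                sid: frozenset(m & self.universe) or frozenset(m)
                for sid, m in ((s, frozenset(v)) for s, v in self.sets.items())
            }

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample ids in header: {dups}")
    values = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            values[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
    groups = pd.read_csv(groups_path, sep="\t", comment="#", dtype=str).set_index("sample_id")
    groups["generation"] = groups["generation"].astype(int)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, groups_path: str | Path
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# scale: log2\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.12g")
    g = matrix.groups.copy()
    g.to_csv(groups_path, sep="\t", index_label="sample_id")


def read_probe_annotation(path: str | Path, uppercase: bool = False) -> dict[str, str | None]:
    """Probe -> gene symbol map; probes with a blank symbol map to None."""
    ann: dict[str, str | None] = {}
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    probe_col, sym_col = df.columns[:2]
    for probe, sym in zip(df[probe_col], df[sym_col]):
        sym = sym.strip()
        if uppercase:
            sym = sym.upper()
        ann[str(probe)] = sym or None
    return ann


def collapse_probes(
    matrix: ExpressionMatrix, annotation: Mapping[str, str | None]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Unmapped probes (absent from the annotation, or mapped to None) are
    dropped; genes measured by several probes get the arithmetic mean of
    their probe rows, per sample.
    """
    symbols = matrix.values.index.map(lambda p: annotation.get(p))
    keep = symbols.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    collapsed = matrix.values.loc[keep].groupby(symbols[keep]).mean()
    if collapsed.empty:
        raise ValueError("collapse_probes: no probe mapped to a gene symbol")
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(values=collapsed, groups=matrix.groups)


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path: str | Path, score_scale: str = "auto") -> pd.DataFrame:
    """Read a STRING-style weighted edge list, normalizing scores to [0, 1].

    ``score_scale``: ``unit`` (already 0-1), ``thousand`` (STRING 0-1000),
    or ``auto`` (any score > 1 is treated as on the 0-1000 scale).
    Self-loops are dropped with a warning; duplicate undirected pairs are
    collapsed keeping the highest score.
    """
    if score_scale not in {"unit", "thousand", "auto"}:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    df.columns = ["node_a", "node_b", "combined_score"][: len(df.columns)]
    score = df["combined_score"].astype(float).to_numpy()
    if score_scale == "thousand":
        score = score / 1000.0
    elif score_scale == "auto":
        score = np.where(score > 1.0, score / 1000.0, score)
    if np.any((score < 0) | (score > 1)):
        bad = score[(score < 0) | (score > 1)][0]
        raise ValueError(f"edge score {bad} outside both the unit and 0-1000 scales")
    df = df.assign(confidence=score).drop(columns=["combined_score"])
    loops = df["node_a"] == df["node_b"]
    if loops.any():
        logger.warning("read_edge_list: dropped %d self-loops", int(loops.sum()))
        df = df.loc[~loops]
    lo = np.minimum(df["node_a"], df["node_b"])
    hi = np.maximum(df["node_a"], df["node_b"])
    df = df.assign(node_a=lo, node_b=hi)
    df = (
        df.groupby(["node_a", "node_b"], as_index=False)["confidence"]
        .max()
        .sort_values(["node_a", "node_b"], ignore_index=True)
    )
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path, score_scale: str = "unit") -> None:
    out = edges.copy()
    score = out["confidence"].to_numpy(dtype=float)
    if score_scale == "thousand":
        score = np.round(score * 1000).astype(int)
    out = out.rename(columns={"confidence": "combined_score"})
    out["combined_score"] = score
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, desc, *members = fields
            sets[set_id] = frozenset(m for m in members if m.strip())
            descriptions[set_id] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection.sets):
            desc = collection.descriptions.get(set_id, "")
            members = "\t".join(sorted(collection.sets[set_id]))
            fh.write(f"{set_id}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# survival tables


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subjects: {dups[:5]}")
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return df


def write_survival_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# result reports


def write_report(table: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a result table with deterministic column order.

    Row order is the caller's documented sort (each stage sorts its own
    output); values survive a TSV round trip to 12 significant digits.
    """
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        records = json.loads(table.to_json(orient="records", double_precision=15))
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise ValueError(f"unknown report format {format!r}")
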