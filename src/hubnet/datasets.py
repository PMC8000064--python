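"""Packaged reference tables from the anti-VEGF-resistant GBM xenograft study.

Three small curated tables ship with the package, transcribed from the
published analysis of the GSE81465 bevacizumab-resistance xenograft series:

* ``common_degs.tsv`` — the 199 genes differential in all three xenograft
  generations, labelled up / down / both (discordant across generations);
* ``deg_classes.gmt`` — functional classes of the fourth-generation DEGs
  (growth factors, cytokines, BMPs, proto-oncogenes, GBM genes,
  receptor-ligand pairs, glycosyl transferases);
* ``hub_genes.tsv`` — the 21 hub genes selected at hybrid centrality > 12,
  split into up- and downregulated.

They serve as worked-example inputs: re-running the partition and
classification operators on them must reproduce the published counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import GeneSetCollection, read_gmt

__all__ = [
    "load_common_deg_table",
    "load_deg_class_sets",
    "load_hub_table",
    "common_deg_records",
]

_DATA = resources.files("hubnet") / "data"


def load_common_deg_table() -> pd.DataFrame:
    """Cross-generation common DEGs with their category (up/down/both)."""
    with resources.as_file(_DATA / "common_degs.tsv") as path:
        return pd.read_csv(path, sep="\t")


def load_deg_class_sets() -> GeneSetCollection:
    """Functional classes of the fourth-generation DEGs as a gene-set collection."""
    with resources.as_file(_DATA / "deg_classes.gmt") as path:
        return read_gmt(path)


def load_hub_table() -> pd.DataFrame:
    """The 21 hub genes with their regulation direction."""
    with resources.as_file(_DATA / "hub_genes.tsv") as path:
        return pd.read_csv(path, sep="\t")


def common_deg_records(generations: tuple[int, ...] = (1, 4, 9)) -> dict[int, pd.DataFrame]:
    """Expand the common-DEG table into per-generation direction records.

    Genes labelled ``up``/``down`` carry that direction in every generation;
    genes labelled ``both`` are given discordant directions (up in all but
    the last generation, down in the last), which is the defining property
    of the category.  Running the cross-generation partition on these
    records reconstructs the published split.
    """
    table = load_common_deg_table()
    out: dict[int, pd.DataFrame] = {}
    for i, gen in enumerate(generations):
        last = i == len(generations) - 1
        direction = [
            c if c in ("up", "down") else ("down" if last else "up")
            for c in table["category"]
        ]
        logfc = [2.0 if d == "up" else -2.0 for d in direction]
        out[gen] = pd.DataFrame(
            {
                "gene": table["gene"],
                "logfc": logfc,
                "t_stat": [8.0 if l > 0 else -8.0 for l in logfc],
                "p_value": 0.001,
                "direction": direction,
            }
        )
    return out
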