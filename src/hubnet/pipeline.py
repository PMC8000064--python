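"""End-to-end orchestration: expression -> DEGs -> partition -> network ->
hubs -> modules -> enrichment -> survival, from one flat config.

Every threshold defaults to the study's value (|logFC| > 1, p < 0.05,
interaction confidence > 0.4, hybrid centrality > 12, MCODE parameters
degree cutoff 2 / node score cutoff 0.2 / k-core 2 / max depth 100, module
score > 5, enrichment count >= 2 at p < 0.05, median survival split), so the
study's configuration is "defaults only".  A JSON manifest records the seed,
every threshold, the normalization mode and per-stage row counts; rerunning
the same config on the same inputs is byte-identical apart from file
timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import degs as degs_mod
from . import mcode, network, survival as surv_mod
from .enrich import enrich as _enrich, tally_directions as _tally_directions
from .io import (
    collapse_probes,
    read_edge_list,
    read_expression_table,
    read_gmt,
    read_probe_annotation,
    read_survival_table,
    write_report,
)

logger = logging.getLogger(__name__)

STAGES = (
    "load_expression",
    "differential_expression",
    "deg_partition",
    "network_construction",
    "hub_selection",
    "module_detection",
    "enrichment",
    "survival_screen",
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one full run; defaults are the study values."""

    expr_path: str = ""
    groups_path: str = ""
    probe_map_path: str | None = None
    edges_path: str = ""
    gmt_path: str = ""
    survival_path: str | None = None
    out_dir: str = "results/run"

    logfc_threshold: float = 1.0
    p_threshold: float = 0.05
    min_confidence: float = 0.4
    hcm_threshold: float = 12.0
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    kcore: int = 2
    max_depth: int = 100
    min_module_score: float = 5.0
    min_count: int = 2
    enrich_p: float = 0.05
    survival_cutoff: float = 0.5
    normalization_mode: str = "default"
    focus_generation: int | None = None
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in fixed order, writing tables and a manifest.

    Returns a dict of in-memory stage results.  A stage failure raises
    :class:`PipelineError` naming the stage; outputs written so far are
    moved under ``<out_dir>/failed``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    results: dict = {}
    current = "?"
    try:
        # -- load_expression ------------------------------------------------
        current = "load_expression"
        if not config.expr_path:
            raise ValueError("expr_path missing from config")
        matrix = read_expression_table(config.expr_path, config.groups_path)
        if config.probe_map_path:
            ann = read_probe_annotation(config.probe_map_path)
            matrix = collapse_probes(matrix, ann)
        results["expression"] = matrix
        manifest["stages"][current] = {
            "n_genes": len(matrix.gene_ids),
            "n_samples": len(matrix.sample_ids),
        }

        # -- differential_expression ---------------------------------------
        current = "differential_expression"
        deg_tables: dict[int, pd.DataFrame] = {}
        for gen in matrix.generations:
            stats = degs_mod.test_differential(matrix, gen)
            deg_tables[gen] = degs_mod.call_degs(
                stats, config.logfc_threshold, config.p_threshold
            )
            called = deg_tables[gen][deg_tables[gen]["direction"] != "none"]
            out = called.reindex(
                called.assign(a=called["logfc"].abs())
                .sort_values(["a", "gene"], ascending=[False, True])
                .index
            )
            write_report(out, out_dir / f"degs_gen{gen}.tsv")
        results["deg_tables"] = deg_tables
        manifest["stages"][current] = {
            f"n_degs_gen{gen}": int((t["direction"] != "none").sum())
            for gen, t in deg_tables.items()
        }

        # -- deg_partition ---------------------------------------------------
        current = "deg_partition"
        partition = degs_mod.partition_common(deg_tables)
        results["partition"] = partition
        (out_dir / "partition.json").write_text(
            json.dumps(
                {
                    "counts": partition.counts(),
                    "up": sorted(partition.up),
                    "down": sorted(partition.down),
                    "both": sorted(partition.both),
                },
                indent=1,
            )
            + "\n"
        )
        manifest["stages"][current] = partition.counts()

        # -- network_construction -------------------------------------------
        current = "network_construction"
        if not config.edges_path:
            raise ValueError("edges_path missing from config")
        gens = matrix.generations
        focus = (
            config.focus_generation
            if config.focus_generation is not None
            else gens[len(gens) // 2]
        )
        focus_degs = deg_tables[focus]
        deg_set = set(focus_degs.loc[focus_degs["direction"] != "none", "gene"])
        edges = read_edge_list(config.edges_path)
        net = network.build_network(
            edges, min_confidence=config.min_confidence, restrict_to=deg_set
        )
        results["network"] = net
        results["focus_generation"] = focus
        manifest["stages"][current] = {
            "focus_generation": int(focus),
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
        }

        # -- hub_selection ----------------------------------------------------
        current = "hub_selection"
        metrics = network.compute_node_metrics(net, mode=config.normalization_mode)
        hubs = network.select_hubs(
            metrics, threshold=config.hcm_threshold, deg_records=focus_degs
        )
        results["metrics"] = metrics
        results["hubs"] = hubs
        write_report(hubs, out_dir / "hubs.tsv")
        manifest["stages"][current] = {
            "normalization_mode": config.normalization_mode,
            "n_hubs": len(hubs),
            "n_up": int((hubs["direction"] == "up").sum()),
            "n_down": int((hubs["direction"] == "down").sum()),
        }

        # -- module_detection -------------------------------------------------
        current = "module_detection"
        modules = mcode.detect_modules(
            net,
            degree_cutoff=config.degree_cutoff,
            node_score_cutoff=config.node_score_cutoff,
            k_core=config.kcore,
            max_depth=config.max_depth,
            min_score=config.min_module_score,
        )
        results["modules"] = modules
        (out_dir / "modules.json").write_text(
            json.dumps(
                [
                    {
                        "seed": m.seed_node,
                        "score": m.score,
                        "density": m.density,
                        "nodes": sorted(m.nodes),
                    }
                    for m in modules
                ],
                indent=1,
            )
            + "\n"
        )
        manifest["stages"][current] = {"n_modules": len(modules)}

        # -- enrichment --------------------------------------------------------
        current = "enrichment"
        if not config.gmt_path:
            raise ValueError("gmt_path missing from config")
        collection = read_gmt(config.gmt_path)
        enrichment = _enrich(
            sorted(deg_set),
            collection,
            min_count=config.min_count,
            p_threshold=config.enrich_p,
        )
        enrichment = _tally_directions(enrichment, focus_degs)
        results["enrichment"] = enrichment
        write_report(enrichment, out_dir / "enrichment.tsv")
        manifest["stages"][current] = {"n_enriched_sets": len(enrichment)}

        # -- survival_screen ---------------------------------------------------
        current = "survival_screen"
        if config.survival_path:
            surv_table = read_survival_table(config.survival_path)
            screened = [g for g in hubs["gene"] if g in surv_table.columns]
            screen = surv_mod.screen_genes(
                surv_table, screened, cutoff_quantile=config.survival_cutoff
            )
            results["survival_screen"] = screen
            write_report(screen, out_dir / "survival_screen.tsv")
            manifest["stages"][current] = {
                "n_screened": len(screen),
                "n_significant": int(screen["significant"].sum()),
            }
        else:
            results["survival_screen"] = None
            manifest["stages"][current] = {"skipped": True}
    except Exception as exc:
        failed = out_dir / "failed"
        failed.mkdir(exist_ok=True)
        for item in sorted(out_dir.iterdir()):
            if item.is_file():
                item.rename(failed / item.name)
        raise PipelineError(f"stage '{current}' failed: {exc}") from exc

    manifest["complete"] = list(manifest["stages"])
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    results["manifest"] = manifest
    return results
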