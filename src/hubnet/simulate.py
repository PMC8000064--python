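"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of a three-generation xenograft
microarray study (shared IgG control replicates, bevacizumab-treated
replicates per generation), a STRING-style confidence-weighted interaction
network with planted dense modules and a planted high-degree hub, a gene-set
collection with planted over-representation, and an exponential survival
cohort whose hazard depends on median-split expression groups.

Every generator is a pure function of its parameters and seed.  One global
seed fans out to independent per-generator streams (seed combined with a
stable per-stream label), so adding a generator call never perturbs the
outputs of earlier calls.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CONTROL,
    TREATED,
    ExpressionMatrix,
    GeneSetCollection,
    write_edge_list,
    write_expression_table,
    write_gmt,
    write_survival_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "simulate_network",
    "simulate_survival",
    "simulate_annotation",
    "simulate_bundle",
]


def stream_rng(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream derived from a global seed and a stable label."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(label.encode()) % 2**31])


@dataclass
class SimulationTruth:
    """Planted ground truth sufficient to score recovery of every stage.

    ``true_deg_labels`` maps generation -> {gene: up/down} for planted genes
    (absent genes are null); ``true_logfc`` the planted log2 fold changes;
    ``planted_modules`` vertex-disjoint node sets added as cliques;
    ``planted_hub_ids`` the planted high-degree nodes; ``enriched_set_ids``
    the gene sets built with planted over-representation;
    ``true_hazard_ratio`` per-gene hazard ratios (1 for non-prognostic).
    """

    true_deg_labels: dict[int, dict[str, str]] = field(default_factory=dict)
    true_logfc: dict[int, dict[str, float]] = field(default_factory=dict)
    planted_modules: list[list[str]] = field(default_factory=list)
    planted_hub_ids: list[str] = field(default_factory=list)
    enriched_set_ids: list[str] = field(default_factory=list)
    true_hazard_ratio: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "SimulationTruth") -> "SimulationTruth":
        return SimulationTruth(
            true_deg_labels={**self.true_deg_labels, **other.true_deg_labels},
            true_logfc={**self.true_logfc, **other.true_logfc},
            planted_modules=self.planted_modules + other.planted_modules,
            planted_hub_ids=self.planted_hub_ids + other.planted_hub_ids,
            enriched_set_ids=self.enriched_set_ids + other.enriched_set_ids,
            true_hazard_ratio={**self.true_hazard_ratio, **other.true_hazard_ratio},
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["true_deg_labels"] = {str(k): v for k, v in d["true_deg_labels"].items()}
        d["true_logfc"] = {str(k): v for k, v in d["true_logfc"].items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    n_genes: int = 20000,
    frac_up: float = 0.02,
    frac_down: float = 0.025,
    effect_logfc: float = 2.0,
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    generations: Sequence[int] = (1, 4, 9),
    discordant_frac: float = 0.075,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Log2 expression for shared controls plus treated replicates per generation.

    A fraction ``frac_up``/``frac_down`` of genes get a planted shift of
    +/-``effect_logfc`` in every generation; a fraction ``discordant_frac`` of
    the planted genes have their sign flipped in one generation to exercise
    the discordant ("both") category.  Defaults mirror the source study's
    magnitudes: ~20k genes, ~900 planted differential genes per generation,
    3 replicates per group, log2 shifts of 2 over noise sd 0.3.
    """
    if not (0 <= frac_up <= 1 and 0 <= frac_down <= 1 and frac_up + frac_down <= 1):
        raise ValueError("frac_up/frac_down must lie in [0,1] and sum to at most 1")
    if effect_logfc <= 1:
        raise ValueError("effect_logfc must exceed the DEG threshold of 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group (variance undefined)")

    rng = stream_rng(seed, "expression")
    width = max(5, len(str(n_genes)))
    genes = np.array([f"g{i:0{width}d}" for i in range(1, n_genes + 1)])
    n_up = int(round(n_genes * frac_up))
    n_down = int(round(n_genes * frac_down))
    order = rng.permutation(n_genes)
    up_idx = order[:n_up]
    down_idx = order[n_up : n_up + n_down]

    base_sign = np.zeros(n_genes)
    base_sign[up_idx] = 1.0
    base_sign[down_idx] = -1.0
    planted = np.concatenate([up_idx, down_idx])
    n_disc = int(round(len(planted) * discordant_frac))
    disc_idx = rng.choice(planted, size=n_disc, replace=False) if n_disc else np.array([], int)
    flip_gen = rng.choice(len(generations), size=n_disc) if n_disc else np.array([], int)

    baseline = baseline_mean + baseline_sd * rng.standard_normal(n_genes)
    cols: dict[str, np.ndarray] = {}
    group_rows = []
    for r in range(1, n_replicates + 1):
        sid = f"ctrl_{r}"
        cols[sid] = baseline + noise_sd * rng.standard_normal(n_genes)
        group_rows.append((sid, CONTROL, 0))

    truth = SimulationTruth()
    for gi, gen in enumerate(generations):
        sign = base_sign.copy()
        flipped = disc_idx[flip_gen == gi]
        sign[flipped] *= -1.0
        shift = sign * effect_logfc
        for r in range(1, n_replicates + 1):
            sid = f"gen{gen}_{r}"
            cols[sid] = baseline + shift + noise_sd * rng.standard_normal(n_genes)
            group_rows.append((sid, TREATED, int(gen)))
        labels = {
            genes[i]: ("up" if sign[i] > 0 else "down") for i in planted
        }
        truth.true_deg_labels[int(gen)] = labels
        truth.true_logfc[int(gen)] = {genes[i]: float(shift[i]) for i in planted}

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    groups = pd.DataFrame(group_rows, columns=["sample_id", "condition", "generation"])
    groups = groups.set_index("sample_id")
    return ExpressionMatrix(values=values, groups=groups), truth


# ---------------------------------------------------------------------------
# interaction network


def simulate_network(
    n_background_nodes: int = 200,
    background_model: tuple[str, float] = ("erdos_renyi", 0.02),
    planted_clique_sizes: Sequence[int] = (6,),
    planted_hub_spokes: int = 50,
    noise_edge_frac: float = 0.0,
    node_names: Sequence[str] | None = None,
    node_prefix: str = "n",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Sparse background graph plus planted cliques and one planted hub.

    Each planted clique is a complete subgraph on fresh nodes attached to the
    background by exactly one bridge edge; the planted hub is one fresh node
    connected to ``planted_hub_spokes`` randomly chosen background nodes.
    All edges carry confidence scores drawn from U(0.5, 1) — above the 0.4
    construction filter — except a requested ``noise_edge_frac`` of
    background edges, which get sub-threshold scores from U(0.05, 0.4).

    ``node_names`` optionally supplies the symbol pool (e.g. planted DEG
    symbols) so the network lives in the same namespace as the expression
    data; it must cover background, cliques, and hub.
    """
    import networkx as nx

    if any(s < 3 for s in planted_clique_sizes):
        raise ValueError("planted clique sizes must be >= 3")
    if planted_hub_spokes < 1:
        raise ValueError("planted hub needs at least one spoke")
    n_extra = sum(planted_clique_sizes) + 1
    n_total = n_background_nodes + n_extra
    if node_names is not None:
        if len(node_names) < n_total:
            raise ValueError(
                f"node budget exceeded: need {n_total} names, got {len(node_names)}"
            )
        names = [str(x) for x in node_names[:n_total]]
    else:
        width = len(str(n_total))
        names = [f"{node_prefix}{i:0{width}d}" for i in range(1, n_total + 1)]

    rng = stream_rng(seed, "network")
    model, param = background_model
    nx_seed = int(rng.integers(2**31 - 1))
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(n_background_nodes, param, seed=nx_seed)
    elif model == "preferential_attachment":
        g = nx.barabasi_albert_graph(n_background_nodes, int(param), seed=nx_seed)
    else:
        raise ValueError(f"unknown background model {model!r}")

    bg_names = names[:n_background_nodes]
    g = nx.relabel_nodes(g, dict(zip(range(n_background_nodes), bg_names)))
    background_edges = set(g.edges())

    truth = SimulationTruth()
    cursor = n_background_nodes
    for size in planted_clique_sizes:
        members = names[cursor : cursor + size]
        cursor += size
        for i in range(size):
            for j in range(i + 1, size):
                g.add_edge(members[i], members[j])
        anchor = bg_names[int(rng.integers(n_background_nodes))]
        g.add_edge(members[0], anchor)
        truth.planted_modules.append(sorted(members))

    hub = names[cursor]
    spokes = min(planted_hub_spokes, n_background_nodes)
    targets = rng.choice(bg_names, size=spokes, replace=False)
    for t in targets:
        g.add_edge(hub, str(t))
    truth.planted_hub_ids.append(hub)

    rows = []
    for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
        if (a, b) in background_edges or (b, a) in background_edges:
            sub = noise_edge_frac > 0 and rng.random() < noise_edge_frac
        else:
            sub = False
        conf = rng.uniform(0.05, 0.4) if sub else rng.uniform(0.5, 1.0)
        rows.append((a, b, round(float(conf), 3)))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    return edges, truth


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    n_subjects: int = 200,
    gene_list: Sequence[str] = ("gene_1",),
    prognostic_genes: Sequence[str] = (),
    hazard_ratio: float = 2.0,
    baseline_rate: float = 0.02,
    censor_rate: float = 0.01,
    seed: int = 0,
    max_attempts: int = 10,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Exponential survival cohort with expression-dependent hazards.

    Each subject gets one standard-normal expression value per gene.  For
    prognostic genes the event hazard is multiplied by ``hazard_ratio`` when
    the subject's expression exceeds that gene's cohort median (multiple
    prognostic genes multiply).  Censoring is independent Exponential
    (``censor_rate``); times are in months.  If any prognostic gene ends up
    with a high or low group containing zero events, the cohort is redrawn
    (warning logged), failing after ``max_attempts``.
    """
    if hazard_ratio <= 0 or baseline_rate <= 0 or censor_rate < 0:
        raise ValueError("hazard_ratio and baseline_rate must be positive")
    unknown = set(prognostic_genes) - set(gene_list)
    if unknown:
        raise ValueError(f"prognostic genes not in gene_list: {sorted(unknown)}")

    genes = [str(g) for g in gene_list]
    prog = [str(g) for g in prognostic_genes]
    for attempt in range(max_attempts):
        rng = stream_rng(seed, f"survival/{attempt}")
        expr = rng.standard_normal((n_subjects, len(genes)))
        hazard = np.full(n_subjects, baseline_rate)
        high_mask = {}
        for j, g in enumerate(genes):
            high = expr[:, j] > np.median(expr[:, j])
            high_mask[g] = high
            if g in prog:
                hazard = hazard * np.where(high, hazard_ratio, 1.0)
        event_time = rng.exponential(1.0 / hazard)
        if censor_rate > 0:
            censor_time = rng.exponential(1.0 / censor_rate, size=n_subjects)
        else:
            censor_time = np.full(n_subjects, np.inf)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)

        ok = True
        for g in prog:
            for grp in (high_mask[g], ~high_mask[g]):
                if event[grp].sum() == 0:
                    ok = False
        if ok:
            break
        logger.warning("simulate_survival: a group had zero events; redrawing cohort")
    else:
        raise RuntimeError(
            f"simulate_survival: no events in a group after {max_attempts} attempts"
        )

    table = pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(1, n_subjects + 1)],
            "time_months": np.round(time, 6),
            "event": event,
        }
    )
    for j, g in enumerate(genes):
        table[g] = np.round(expr[:, j], 6)
    truth = SimulationTruth(
        true_hazard_ratio={g: (hazard_ratio if g in prog else 1.0) for g in genes}
    )
    return table, truth


# ---------------------------------------------------------------------------
# gene-set annotation


def simulate_annotation(
    universe: Sequence[str],
    n_sets: int = 100,
    set_size_range: tuple[int, int] = (10, 50),
    enriched_sets: Sequence[tuple[Sequence[str], int]] = (),
    seed: int = 0,
) -> tuple[GeneSetCollection, SimulationTruth]:
    """Gene-set collection with planted over-representation.

    ``enriched_sets`` is a sequence of ``(target_query, overlap_count)``
    pairs; each produces one set containing exactly ``overlap_count`` members
    of the target query, padded from the rest of the universe.  The remaining
    sets are drawn uniformly from the universe (null sets).
    """
    universe = [str(g) for g in universe]
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("universe smaller than the largest requested set size")
    rng = stream_rng(seed, "annotation")
    uni = np.array(universe)

    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    truth = SimulationTruth()
    for i, (target_query, overlap_count) in enumerate(enriched_sets, start=1):
        query = [str(g) for g in target_query]
        size = int(rng.integers(lo, hi + 1))
        size = max(size, overlap_count)
        if overlap_count > min(size, len(query)):
            raise ValueError("overlap_count exceeds set size or query size")
        inside = rng.choice(query, size=overlap_count, replace=False)
        pool = np.array(sorted(set(universe) - set(query)))
        if size - overlap_count > len(pool):
            raise ValueError("universe too small to pad the enriched set")
        outside = rng.choice(pool, size=size - overlap_count, replace=False)
        sid = f"enriched_{i:03d}"
        sets[sid] = frozenset(map(str, np.concatenate([inside, outside])))
        descriptions[sid] = f"planted enrichment ({overlap_count}/{size})"
        truth.enriched_set_ids.append(sid)

    n_null = n_sets - len(enriched_sets)
    for i in range(1, n_null + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni, size=size, replace=False)
        sid = f"null_{i:04d}"
        sets[sid] = frozenset(map(str, members))
        descriptions[sid] = "null set"

    coll = GeneSetCollection(
        sets=sets, descriptions=descriptions, universe=frozenset(universe)
    )
    return coll, truth


# ---------------------------------------------------------------------------
# full bundle


def simulate_bundle(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_genes: int = 20000,
    n_background_nodes: int = 700,
    clique_size: int = 8,
    hub_spokes: int = 60,
    n_sets: int = 100,
    n_subjects: int = 300,
    prognostic_hr: float = 2.5,
) -> dict:
    """Generate a coordinated set of pipeline inputs sharing one gene namespace.

    The interaction network is built over symbols planted as differential in
    the middle generation (the network stage restricts to called DEGs, so
    planted structures must live inside the DEG universe); the gene-set
    collection plants one over-represented set against the same symbols; the
    survival cohort plants the hub gene as prognostic.  Defaults mirror the
    study's magnitudes: ~20k genes, ~900 planted DEGs, a ~700-node network
    with ~5k edges.
    """
    matrix, expr_truth = simulate_expression(n_genes=n_genes, seed=seed)
    gens = matrix.generations
    mid_gen = gens[len(gens) // 2]
    labels = expr_truth.true_deg_labels[mid_gen]
    # concordant planted genes only: discordant ones may flip out of the
    # mid-generation DEG set in other generations, but stay DEGs in mid gen
    deg_symbols = sorted(labels)

    edges, net_truth = simulate_network(
        n_background_nodes=n_background_nodes,
        planted_clique_sizes=(clique_size,),
        planted_hub_spokes=hub_spokes,
        node_names=deg_symbols,
        seed=seed,
    )

    query = deg_symbols
    coll, ann_truth = simulate_annotation(
        universe=list(matrix.gene_ids),
        n_sets=n_sets,
        set_size_range=(20, 60),
        enriched_sets=[(query, 20)],
        seed=seed,
    )

    hub_gene = net_truth.planted_hub_ids[0]
    surv_genes = [hub_gene] + deg_symbols[:9]
    surv_genes = list(dict.fromkeys(surv_genes))
    surv, surv_truth = simulate_survival(
        n_subjects=n_subjects,
        gene_list=surv_genes,
        prognostic_genes=[hub_gene],
        hazard_ratio=prognostic_hr,
        seed=seed,
    )

    truth = expr_truth.merge(net_truth).merge(ann_truth).merge(surv_truth)
    bundle = {
        "expression": matrix,
        "edges": edges,
        "collection": coll,
        "survival": surv,
        "truth": truth,
        "mid_generation": mid_gen,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_table(matrix, out / "expression.tsv", out / "samples.tsv")
        write_edge_list(edges, out / "edges.tsv")
        write_gmt(coll, out / "genesets.gmt")
        write_survival_table(surv, out / "survival.tsv")
        truth.to_json(out / "truth.json")
    return bundle
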