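# Methods

## Study design being modelled

The pipeline reproduces a common systems-biology workflow for resistance
mechanisms: bulk expression profiles from serially passaged tumor
xenografts under sustained anti-VEGF treatment (generations 1, 4 and 9,
three treated replicates each) are compared against three shared IgG
control replicates; genes that change consistently across generations are
mapped onto a protein–protein interaction network; topologically central
genes ("hubs") and dense modules are nominated as candidate drivers; and
hubs are screened for association with patient survival. The package
implements each analytical step as a tested library operation and supplies
synthetic inputs with planted ground truth in place of the external
sources (microarray repository, interaction database, clinical cohort).

## Differential expression

`logFC` is the difference of group means on log2-scale intensities
(treated − control). The per-gene statistic is a two-sided Welch t-test;
with three replicates per group this is deliberately simple and
conservative. A moderated mode shrinks each group's per-gene variance
toward the median variance across genes (`(1−w)·s²_g + w·median(s²)`),
approximating empirical-Bayes pipelines without claiming bit
compatibility: the original analysis used a web tool whose fitted model
internals are not recoverable, only its thresholds.

Calls use strict thresholds: up iff `logFC > 1` and `p < 0.05`, down iff
`logFC < −1` and `p < 0.05`. A gene at exactly the threshold is not a DEG.
No multiple-testing correction is applied by default (the thresholds above
are raw-p by design); Benjamini–Hochberg is available on the enrichment
side. Degenerate rows with zero variance in both groups get `p = 1` when
the means agree and `p = 0` otherwise, which makes the zero-noise limit of
the simulator exactly recoverable. Rows with missing values in a compared
group are excluded from that comparison and logged.

The cross-generation partition intersects the per-generation DEG sets: a
common gene is up (down) when its direction agrees in every generation and
discordant ("both") otherwise. The partition is invariant to generation
order; up/down/both are disjoint and exhaustive over the common set (both
properties asserted at run time).

## Network construction and the hub score

Edges with confidence strictly above 0.4 (scores auto-normalized from the
0–1000 convention) whose endpoints both lie in the focus generation's DEG
set form a simple undirected graph; isolated query genes are retained but
flagged. Centralities are computed on unweighted shortest paths — edge
confidence acts as a filter, not a distance — via networkx: raw degree,
per-component closeness `(n_c−1)/Σd`, Brandes betweenness, and the
arithmetic mean of neighbor degrees (0, flagged, for isolated nodes).

The hub score is the plain sum of the four terms. Because the terms have
incommensurate scales, the sum is computed under a declared mode stamped
into every output: the default keeps degree and mean neighbor degree raw
and normalizes closeness and betweenness into [0, 1], which is the only
reading under which a fixed threshold like 12 is meaningful (degree-scale
terms dominate). `all_raw` and `all_normalized` modes exist because the
original description does not state its normalization. Note that the
absolute threshold couples to network density: on the synthetic network
(~900 nodes, ~5000 edges, mean degree ~11) most connected nodes exceed 12,
so hub *rank* (the planted hub attains rank 1) is the meaningful recovery
criterion there, while the threshold is kept at its study value.

## Module detection

The detector follows the molecular-complex-detection scheme with the
Cytoscape-default variant pinned: vertex weight = highest-k-core number ×
density of that core over the node's closed neighborhood (nodes under the
degree cutoff of 2 weigh 0); greedy breadth-first growth from unvisited
seeds in descending weight, admitting a neighbor when its weight is at
least `(1 − 0.2) ×` the seed weight, to depth ≤ 100, with single
membership (visited rule); post-processing discards candidates without a
2-core, applies a single-pass haircut of within-module degree-1 nodes, and
rescores. Score = induced density × node count; the downstream filter
keeps score > 5 (strict). Seed ties and neighbor iteration are
lexicographic by symbol, making module sets independent of node ordering.

## Enrichment

One-sided hypergeometric upper tail (equivalent to Fisher exact, greater),
computed by `scipy.stats.hypergeom`. The universe defaults to the union of
all sets plus the query, and can be overridden; the original analysis ran
on a web service whose background is unknown, so its printed enrichment
p-values are treated as non-reproducible. The overlap filter is `count ≥ 2`
inclusive: the methods wording "count > 2" conflicts with printed result
rows at count 2, and the printed results are taken as authoritative. An
EASE-style variant (score k−1) is available behind a flag.

## Survival screen

Expression is dichotomized at the median (configurable quantile); subjects
exactly at the cut go to the low group — a deterministic rule recorded in
the output. Kaplan–Meier curves, the Mantel–Haenszel log-rank test and the
Cox proportional-hazards fit (single binary covariate, Efron ties, Wald
95% CI) are delegated to lifelines. A gene is significant when the
log-rank p or the hazard-ratio p is ≤ 0.05 (inclusive, per the screen's
dual criterion). Times are months. Per-group median survival is reported
for transparency, since "survival rate in months" in the tabulated source
is otherwise ambiguous.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their parameters and a seed; one
global seed fans out to per-generator streams keyed by a stable label, so
adding a call never perturbs earlier outputs.

* **Expression** — baseline gene levels `N(8, 1.5²)` plus i.i.d. Gaussian
  noise (sd 0.3) on the log2 scale; planted shifts of ±2 for 2% up / 2.5%
  down of genes (≈900 DEGs among 20k, the study's magnitude); 7.5% of
  planted genes flip sign in one generation to exercise the discordant
  category (the printed common-DEG table is ~7.5% discordant). Controls
  are shared across generations, as in the study design. Not emulated:
  probe-level bead noise, intensity-dependent variance, batch effects,
  correlated genes — so passing recovery tests shows threshold logic and
  statistics are right, not that real microarray noise is handled.
* **Network** — Erdős–Rényi (or preferential-attachment) background with
  planted cliques on fresh nodes (one bridge edge each) and one planted
  spoke hub; edge confidences U(0.5, 1), optionally a sub-threshold noise
  fraction. Not emulated: STRING's evidence channels, degree
  heterogeneity of real interactomes.
* **Annotation** — null sets drawn uniformly from the universe; enriched
  sets contain an exact planted overlap with a target query.
* **Survival** — exponential event times with hazard multiplied by the
  planted ratio for above-median expression of prognostic genes,
  independent exponential censoring. Cohorts where a prognostic gene has
  an event-free group are redrawn (at most 10 times, logged).

## Problem sizes and numerical choices

The recovery and calibration suites use desk-scale sizes chosen as the
package's own defaults: DEG recovery on 2k genes × 20 seeds (sensitivity
and FDP do not depend materially on gene count at fixed effect and noise);
clique recovery with 6-cliques on ER(100, 0.03) × 20 seeds; log-rank null
calibration with 500 cohorts of n=200; hazard-ratio bias with 30 cohorts
of n=500 per planted ratio; end-to-end runs at the full study scale (20k
genes, ~900-DEG network with ~5k edges) × 10 seeds.

The null-enrichment calibration uses universe 5000, query 500, set sizes
200–500 over 1000 sets. The exact test is discrete and conservative: its
attainable level just below 0.05 depends on the overlap lattice. This
configuration's exact attainable level is ≈0.042 (computed analytically
from the hypergeometric tail), so the empirical rate lands near 0.04;
with small sparse sets the same correct implementation would reject far
less often than 0.05 purely through discreteness.

Tolerances: centralities are compared to brute-force BFS/path-counting
oracles at 1e-9; hypergeometric tails to closed-form combinatorial sums at
1e-12; the toy Cox fit to an analytic score-equation root at 1e-3 (the
iterative fitter's own convergence tolerance dominates there).

## Known limitations

* The Welch default will differ from moderated-t pipelines near the p
  threshold at n=3; the study's exact per-generation DEG counts from the
  deposited series are therefore not a target, and reproducing them would
  additionally require the original preprocessing and annotation versions.
* Published hub lists and module compositions depend on a specific
  interaction-database version and are likewise out of reach by design;
  the packaged printed tables stand in as fixed worked examples.
* The HCM threshold's meaning depends on the normalization mode and
  network scale; the mode is therefore stamped into all outputs rather
  than hidden.
* Enrichment p-values from annotation web services are not reproducible
  without their background universes; only the test itself is validated
  (against enumeration and on planted/null collections).
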