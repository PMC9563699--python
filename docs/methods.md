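# Methods

This note documents the models, conventions and numerical choices behind
`coexnet`, and what the synthetic benchmark does and does not demonstrate.

## Inputs and identifier handling

Expression matrices are assumed normalized (and, across cohorts,
batch-corrected) upstream; `coexnet` performs no normalization, imputation
or probe collapsing. Missing or non-numeric cells are hard errors. Gene
and sample identifiers are whitespace-stripped but case-sensitive, and
genes are matched across layers by exact string: symbol harmonization
across platforms is the user's responsibility. Layer↔annotation pairing is
positional in the config, never inferred from filenames. Delimiter
auto-detection considers tab and comma only.

## Variance filter and the inflection suggestion

Genes are ranked by descending sample variance (ties broken by
lexicographic gene ID, for determinism). The suggested top-variant count
is derived from the ranked log₁₀-variance curve: the curve is smoothed
with a centered moving average (window = max(5, 1% of genes), forced odd,
applied only where the full window fits so a linear curve has exactly zero
curvature), and the suggestion is the rank with the largest |discrete
second difference| of the smoothed curve — the strongest inflection. All
local curvature maxima are available via `inflection_ranks`. Degenerate
curves (shorter than the window, or with no curvature above a relative
tolerance of 1e-9 of the curve's range) fall back to the full gene count
with a warning. Because multiplying all variances by a positive constant
only shifts the log curve, the suggestion is scale-equivariant.

## Correlations

Pearson and Spearman (average-rank ties) coefficients are computed for all
gene pairs by matrix algebra on centered/ranked rows, clipped into
[−1, 1]; agreement with per-pair reference routines is tested to 1e−12.
Constant genes have undefined correlation: they carry a NaN marker against
every partner and can never form edges. Self-pairs are excluded.
Precomputed symmetric matrices can be wrapped instead.

## Cut-off statistics and the scale-free score

For each candidate threshold c (default grid: 50 evenly spaced values in
[0.9, 1.0]) the graph with edges {ρ ≥ c} is formed on the *signed*
coefficient — negative co-expression is outside the model — with an
inclusive comparison, so a pair at exactly the stated cut-off keeps its
edge. Isolated genes are excluded. Recorded per cut-off: edge count, node
count, connected-component count, and the scale-free topology score R²:
the coefficient of determination of the least-squares fit of
log₁₀(frequency) on log₁₀(degree) over *distinct* positive degrees (raw
frequencies, not binned, not cumulative — a convention choice, documented
as such). With fewer than two distinct degrees R² is undefined (NaN); when
the log-frequencies are constant across ≥2 distinct degrees the horizontal
fit is exact and R² is reported as 1.0 (the 1 − SSres/SStot form is
indeterminate there).

The cut-off choice is the analyst's; the tool writes the guide table. The
convenience heuristic `suggest_cutoff` — maximize R² among cut-offs whose
network retains at least 90% of the maximum node count on the grid, ties
to the lower cut-off — encodes "maximize scale-free fit while keeping as
many genes as possible" and is labeled heuristic.

## Group Fold-Change

GFCs are raw ratios, never logged or capped by default (a log2 flag
exists, off by default). In no-control mode each group mean is divided by
the unweighted mean of the gene's group means, so each gene's GFCs average
exactly 1 — an algebraic identity the tests assert to 1e−9. In
with-control mode each group mean is divided by the control group's mean,
computed within each layer independently, so unbalanced designs across
layers do not leak into each other. A zero denominator makes the gene's
GFC row NaN with a warning; NaN propagates into (and is excluded from)
module summaries, never silently replaced by an epsilon. Means are taken
on the values as given; whether those are linear- or log-scale is the
caller's modeling decision.

## Networks and integration

Edges carry the correlation as weight and a provenance map
{layer → original weight}. Union integration takes the union of node and
edge sets; intersection integration keeps exactly the reference network's
topology and annotates each edge with its weight in every other layer
where present. Multi-edge weights are resolved by min (default — the
conservative lower bound on the shared co-expression, which also thins the
network before clustering), mean or max, always computed over the layers
that contain the edge: absence is structural, not weight zero. In
intersection mode the resolved weight is recomputed by policy over present
layers while the reference's own weight is kept as `reference_weight` —
both readings of "the integrated weight" stay queryable. Exports are
GraphML (round-trippable, per-layer weight attributes, optional module
attribute) and a Cytoscape-friendly TSV edge list with one column per
layer (NA where absent).

## Module detection and summaries

Leiden on weighted modularity (resolution 1.0, seed 1, iterated to
convergence) is the default; Louvain, fast-greedy and edge-betweenness are
alternatives. Seeds and parameters are recorded in the partition and the
run record. Modules below the minimum size (default 25 genes) are
dissolved into the unassigned pool. Labels are drawn from a fixed color
vocabulary in descending size order (ties anchored at the
lexicographically smallest member), making the label sequence a pure
function of partition structure. Module summaries average the *defined*
GFCs of a module's genes per (layer, group); genes unmeasured in a layer
contribute nothing there. Condition columns are ordered by agglomerative
hierarchical clustering on Euclidean distances between mean-GFC profiles
— complete linkage by default (the linkage is configurable; nothing in the
method fixes it) — with a pairwise-complete, rescaled distance and a
warning when cells are undefined. Hub genes default to weighted degree on
the module-induced subgraph (degree and betweenness exposed); hubness has
no canonical definition, and weighted degree is the simplest defensible
one. All rankings break ties lexicographically.

## Enrichment

One-sided hypergeometric upper-tail over-representation (no depletion
testing), with module and gene sets intersected with the universe first.
The default universe in the pipeline is the integrated network's gene set
— the object actually being interpreted — overridable to all measured
genes. Benjamini–Hochberg adjustment (via `statsmodels`) is applied per
module across one collection's sets, matching per-module top-term
reporting: the default filter keeps terms with adjusted p ≤ 0.1, at most
the 5 smallest per module, ties resolved by raw p then set name.
TF-target enrichment is the identical offline test on user-supplied
TF-target GMTs — no web service is ever called — and additionally reports
which target pairs are connected in the integrated network.

## Synthetic benchmark

The generator plants modules with a single latent factor per module,
layer and sample: a module gene's value is
`effect(module, group) · base + sd · (√ρ · f + √(1−ρ) · ε)` with
ρ = within-module correlation (default 0.95), base = 10, sd = 1, so
within-group pairwise correlation is ρ and the with-control GFC of a
module equals its effect ratio in expectation. Background genes are
independent noise around the base. Defaults — 2 layers, 5 modules × 40
genes, 200 background genes, groups ctrl/A/B with 10 samples each — are
the standard benchmark conditions used throughout the tests and the
acceptance script; the default effect map assigns each module one affected
non-control group (module M1: 2.0× in A; then 0.5, 1.5, 0.75, 1.25 cycling)
so module ranking by mean GFC has a known answer. All randomness flows
from a single seed; matrices regenerate bit-identically.

What the benchmark emulates: shared gene namespace across layers,
block-correlated expression, group-dependent mean shifts, positive
normalized values. What it does not: platform-specific distributions
(counts vs intensities), partial gene overlap between layers, outlier
samples, correlated background structure. Passing the end-to-end recovery
test therefore demonstrates the pipeline's internal correctness and
determinism, not performance on real cross-platform cohorts, where
correlation strength, module separation and the right cut-off are all
data-dependent.

## Problem sizes and determinism

The test suite and acceptance script run the full pipeline on the 400-gene
two-layer benchmark, oracle grids on universes up to 25 genes, 100 random
graphs for the R² oracle, 1000 random vectors for the BH oracle, and 50
random two-layer instances for the integration algebra — sizes at which
every check is exact or tight while the whole suite completes in seconds.
Pipeline reruns with identical config and seed produce byte-identical
partition and summary tables; the run record (parameters, seeds, library
versions, SHA-256 input digests) plus the inputs reproduce every artifact.
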