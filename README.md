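# coexnet

Horizontal integration of bulk transcriptomics datasets through weighted
gene co-expression networks.

## The problem

Combining several expression datasets that measure the same genes — e.g. a
microarray study and an RNA-seq study of the same biological system — is
hard on the level of the raw values: platforms differ in scale, dynamic
range and measurement noise, and naive concatenation lets the noisiest
dataset dominate. `coexnet` sidesteps this by *transformation-based*
integration: each dataset ("layer") is first converted into a weighted
gene co-expression network, and the networks — which all speak the common
language of genes and correlations — are then combined. The tool is aimed
at computational biologists who want joint co-expression modules, per-
condition fold-change summaries, and functional enrichment across cohorts
or platforms without re-normalizing data onto a common scale.

## Method

For each layer (a normalized, batch-corrected gene × sample matrix plus a
sample annotation table with a grouping column):

1. **Variance filter** — keep the top-*n* most variant genes; *n* can be
   set per layer or suggested from the inflection of the ranked
   log-variance curve (`suggest_topvar`).
2. **Correlation** — all pairwise Pearson or Spearman coefficients
   ρ(g₁, g₂) (precomputed matrices are also accepted).
3. **Cut-off guide** — for a grid of candidate thresholds (default 50
   values in [0.9, 1.0]) tabulate edge count, node count, component count
   and the scale-free topology score R² of the fit
   log₁₀ freq(k) ~ log₁₀ k over the node-degree distribution. The user
   picks the cut-off; a labeled heuristic default maximizes R² while
   retaining ≥ 90% of the attainable nodes.
4. **Group Fold-Change (GFC)** — with group labels x ∈ X and
   mean_g(x) the mean expression of gene g in group x:
   - no controls: GFC(g, xᵢ) = mean_g(xᵢ) / ((1/|X|) Σⱼ mean_g(xⱼ))
   - with controls: GFC(g, xᵢ) = mean_g(xᵢ) / mean_g(x_c), per layer.
5. **Network** — edge for every pair with ρ ≥ cut-off (inclusive, positive
   correlations only), edge weight = ρ.

Layer networks are integrated by **union** (all nodes and edges; the
holistic view) or **intersection** (one layer's network is the reference
and every edge is annotated with its weight in the other layers). An edge
present in several layers gets the **min** (default), mean or max of its
per-layer weights; full provenance is kept. The integrated network is
clustered (Leiden by default, seeded), modules below 25 genes are
dissolved, and modules are labeled with color names by descending size,
summarized by mean GFC per (layer, condition), and interpreted by
one-sided hypergeometric over-representation against GMT gene-set
collections (Benjamini–Hochberg adjusted per module; top 5 terms with
adjusted p ≤ 0.1 reported). TF-target libraries run through the same
machinery. Hub genes are ranked by weighted degree within the module
subgraph.

## Worked example

`coexnet` ships a seeded generator of multi-layer data with planted
co-expression modules (latent-factor Gaussian model) so the whole pipeline
can be exercised without downloads:

```python
import coexnet as cx

layers, annotations, truth = cx.standard_fixture(seed=1)
corr = cx.compute_correlations(layers[0], method="spearman")
stats = cx.cutoff_statistics(corr)          # 50 cut-offs in [0.9, 1.0]
cutoff = cx.suggest_cutoff(stats)
print(f"chosen cut-off: {cutoff:.3f}")

nets = [
    cx.build_network(cx.compute_correlations(lay, "spearman"), cutoff)
    for lay in layers
]
integrated = cx.integrate_union(nets, policy="min")
print(f"integrated network: {integrated.n_nodes} nodes, {integrated.n_edges} edges")

partition = cx.filter_min_size(cx.detect_modules(integrated, seed=1), min_size=25)
print(f"modules: {partition.sizes()}")

gfcs = [cx.compute_gfc(lay, ann) for lay, ann in zip(layers, annotations)]
summary = cx.module_summary(partition, gfcs)
print(summary.table.round(2).to_string())
```

prints

```
chosen cut-off: 0.902
integrated network: 200 nodes, 3900 edges
modules: {'turquoise': 40, 'blue': 40, 'brown': 40, 'yellow': 40, 'green': 40}
          layer1             layer2
            ctrl     A     B   ctrl     A     B
turquoise    1.0  1.94  0.95    1.0  1.96  1.04
blue         1.0  0.97  0.58    1.0  0.97  0.53
brown        1.0  1.49  0.95    1.0  1.43  0.98
yellow       1.0  1.00  0.75    1.0  1.10  0.81
green        1.0  1.27  1.03    1.0  1.32  1.02
```

The five planted 40-gene modules are recovered exactly (the 200 background
genes never reach the 0.9 correlation threshold and drop out of the
network), and the module mean-GFC table recovers the planted condition
effects: the `turquoise` module was generated with a 2.0-fold effect in
group A relative to control, `blue` with a 0.5-fold effect in group B, and
so on, consistently across both layers. The control column is 1 by
construction of the with-control GFC.

The same analysis runs from the shell on TSV inputs:

```sh
coexnet cutoffs -c config.yaml        # write the cut-off guide tables only
coexnet run -c config.yaml            # full pipeline + run_record.json
coexnet satellite suggest_topvar -c config.yaml
```

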