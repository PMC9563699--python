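"""Config-driven end-to-end pipeline and satellite functions.

The pipeline mirrors the three analysis phases:

1. **pre-integration** (per layer): variance filter → pairwise correlation
   → cut-off statistics → GFC → layer network;
2. **integration**: union or reference-anchored intersection of the layer
   networks with a multi-edge weight policy;
3. **post-integration**: community detection → minimum-size filter →
   module mean-GFC summary → optional gene-set and TF-target enrichment.

:func:`run_analysis` executes the phases in memory on an
:class:`~coexnet.io.AnalysisState`; :func:`run_pipeline` wraps it with file
I/O, artifact writing and a machine-readable run record (all parameters,
seeds, library versions and input digests), so a run is reproducible from
the record plus the input files alone. Satellite functions (variance-count
suggestion, hub genes, PCA score table, expression distribution table) run
independently of the main flow but declare the stages they depend on.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    ALGORITHMS,
    detect_modules,
    filter_min_size,
    hub_genes,
    module_summary,
    order_conditions,
)
from .enrichment import enrich_modules, tf_enrichment, top_terms
from .gfc import compute_gfc, write_gfc
from .io import (
    AnalysisState,
    ValidationError,
    read_annotation,
    read_expression,
    read_gmt,
    validate_state,
)
from .network import (
    POLICIES,
    build_network,
    integrate_intersection,
    integrate_union,
    write_edgelist,
    write_graphml,
)
from .preprocess import (
    compute_correlations,
    cutoff_statistics,
    default_cutoff_grid,
    filter_top_variant,
    rank_variances,
    suggest_cutoff,
    suggest_topvar,
)

__all__ = [
    "LayerConfig",
    "RunConfig",
    "PipelineStageError",
    "run_analysis",
    "run_pipeline",
    "run_satellite",
    "SATELLITES",
]

logger = logging.getLogger("coexnet")
if not logger.handlers:  # stderr logging with per-stage timing
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class LayerConfig:
    """Input paths and per-layer settings for one dataset."""

    name: str
    expression: str
    annotation: str
    grouping_column: str
    control_label: Optional[str] = None
    top_variant: object = "all"  # int, "all", or "suggest"
    cutoff: object = "suggest"  # float or "suggest"
    delimiter: Optional[str] = None


@dataclass
class RunConfig:
    """Declarative description of a full analysis run."""

    layers: list[LayerConfig]
    correlation_method: str = "spearman"
    cutoff_grid: dict = field(
        default_factory=lambda: {"low": 0.9, "high": 1.0, "n": 50}
    )
    integration_mode: str = "union"  # union | intersection
    edge_policy: str = "min"  # min | mean | max
    reference_layer: Optional[str] = None
    clustering_algorithm: str = "leiden"
    resolution: float = 1.0
    seed: int = 1
    min_module_size: int = 25
    gfc_log2: bool = False
    enrichment_collections: dict = field(default_factory=dict)  # name -> GMT path
    tf_collections: dict = field(default_factory=dict)  # name -> GMT path
    enrichment_top_n: int = 5
    enrichment_alpha: float = 0.1
    output_dir: str = "coexnet_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        layers = [LayerConfig(**lay) for lay in raw.pop("layers")]
        return cls(layers=layers, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "layers"}
        d["layers"] = [dict(lay.__dict__) for lay in self.layers]
        return d

    def validate(self) -> None:
        """Check everything checkable before any computation starts."""
        if not self.layers:
            raise ValidationError("config must define at least one layer")
        names = [lay.name for lay in self.layers]
        if len(set(names)) != len(names):
            raise ValidationError(f"layer names not unique: {names}")
        for lay in self.layers:
            for p in (lay.expression, lay.annotation):
                if not Path(p).exists():
                    raise ValidationError(f"layer {lay.name!r}: file not found: {p}")
            if not (lay.top_variant in ("all", "suggest") or isinstance(lay.top_variant, int)):
                raise ValidationError(
                    f"layer {lay.name!r}: top_variant must be an int, 'all' or 'suggest'"
                )
            if not (lay.cutoff == "suggest" or isinstance(lay.cutoff, (int, float))):
                raise ValidationError(
                    f"layer {lay.name!r}: cutoff must be a number or 'suggest'"
                )
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError(f"unknown correlation method {self.correlation_method!r}")
        if self.integration_mode not in ("union", "intersection"):
            raise ValidationError(
                f"unknown integration mode {self.integration_mode!r} "
                "(expected 'union' or 'intersection')"
            )
        if self.edge_policy not in POLICIES:
            raise ValidationError(f"unknown edge policy {self.edge_policy!r}")
        if self.integration_mode == "intersection":
            if self.reference_layer is None:
                raise ValidationError("intersection mode requires reference_layer")
            if self.reference_layer not in names:
                raise ValidationError(
                    f"reference layer {self.reference_layer!r} not among layers {names}"
                )
        if self.clustering_algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown clustering algorithm {self.clustering_algorithm!r}; "
                f"choose from {ALGORITHMS}"
            )
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")
        for group in (self.enrichment_collections, self.tf_collections):
            for cname, path in group.items():
                if not Path(path).exists():
                    raise ValidationError(f"collection {cname!r}: file not found: {path}")


# ---------------------------------------------------------------------------
# Core analysis (in memory)
# ---------------------------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_analysis(state: AnalysisState, config: RunConfig) -> AnalysisState:
    """Execute the three analysis phases on an in-memory state.

    Fills the state's result slots (variance curves, correlations, cutoff
    statistics, GFC tables, layer networks, integrated network, partition,
    module summary, enrichments) and records every consumed parameter.
    """
    state.parameters.update(config.to_dict())
    grid = default_cutoff_grid(**config.cutoff_grid)

    @_stage("preprocess")
    def _preprocess():
        curves, filtered = {}, []
        for (layer, annotation), lconf in zip(state.layers, config.layers):
            curve = rank_variances(layer)
            curves[layer.name] = curve
            n = lconf.top_variant
            if n == "suggest":
                n = suggest_topvar(curve)
            elif n == "all":
                n = None
            filtered.append((filter_top_variant(layer, n), annotation))
        return curves, filtered

    curves, filtered = _preprocess()
    state.set_result("variance_curves", curves)

    @_stage("correlation")
    def _correlate():
        return {
            layer.name: compute_correlations(layer, config.correlation_method)
            for layer, _ in filtered
        }

    correlations = _correlate()
    state.set_result("correlations", correlations)

    @_stage("cutoff_statistics")
    def _cutoffs():
        stats_by_layer, chosen = {}, {}
        for (layer, _), lconf in zip(filtered, config.layers):
            st = cutoff_statistics(correlations[layer.name], grid)
            stats_by_layer[layer.name] = st
            if lconf.cutoff == "suggest":
                chosen[layer.name] = suggest_cutoff(st)
            else:
                chosen[layer.name] = float(lconf.cutoff)
        return stats_by_layer, chosen

    stats_by_layer, chosen_cutoffs = _cutoffs()
    state.set_result("cutoff_statistics", stats_by_layer)
    state.parameters["chosen_cutoffs"] = chosen_cutoffs

    @_stage("gfc")
    def _gfc():
        return [
            compute_gfc(layer, annotation, log2=config.gfc_log2)
            for layer, annotation in filtered
        ]

    gfc_tables = _gfc()
    state.set_result("gfc", gfc_tables)

    @_stage("layer_networks")
    def _networks():
        return {
            layer.name: build_network(
                correlations[layer.name], chosen_cutoffs[layer.name]
            )
            for layer, _ in filtered
        }

    layer_networks = _networks()
    state.set_result("layer_networks", layer_networks)

    @_stage("integration")
    def _integrate():
        nets = list(layer_networks.values())
        if config.integration_mode == "union":
            return integrate_union(nets, policy=config.edge_policy)
        return integrate_intersection(
            nets, reference=config.reference_layer, policy=config.edge_policy
        )

    integrated = _integrate()
    state.set_result("integrated_network", integrated)

    @_stage("clustering")
    def _cluster():
        raw = detect_modules(
            integrated,
            algorithm=config.clustering_algorithm,
            resolution=config.resolution,
            seed=config.seed,
        )
        return filter_min_size(raw, config.min_module_size)

    partition = _cluster()
    state.set_result("partition", partition)

    @_stage("module_summary")
    def _summary():
        summary = module_summary(partition, gfc_tables)
        if summary.table.shape[1] >= 2:
            summary = order_conditions(summary)
        return summary

    state.set_result("module_summary", _summary())

    @_stage("enrichment")
    def _enrich():
        universe = set(integrated.graph.nodes)
        out = {}
        for cname, path in config.enrichment_collections.items():
            res = enrich_modules(partition, read_gmt(path), universe)
            out[cname] = {
                "all": res,
                "top": top_terms(res, n=config.enrichment_top_n, alpha=config.enrichment_alpha),
            }
        for cname, path in config.tf_collections.items():
            res = tf_enrichment(partition, read_gmt(path), universe, network=integrated)
            out[cname] = {
                "all": res,
                "top": top_terms(res, n=config.enrichment_top_n, alpha=config.enrichment_alpha),
            }
        return out

    if config.enrichment_collections or config.tf_collections:
        state.set_result("enrichments", _enrich())
    return state


# ---------------------------------------------------------------------------
# File-level pipeline
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_state(config: RunConfig) -> AnalysisState:
    """Read all configured layers/annotations and validate their pairing."""
    layers, annotations = [], []
    for lconf in config.layers:
        layers.append(
            read_expression(lconf.expression, delimiter=lconf.delimiter, name=lconf.name)
        )
        annotations.append(
            read_annotation(
                lconf.annotation,
                grouping_column=lconf.grouping_column,
                control_label=lconf.control_label,
                delimiter=lconf.delimiter,
            )
        )
    return validate_state(layers, annotations)


def run_pipeline(config: RunConfig) -> Path:
    """Validate, run the full analysis and write all artifacts.

    Writes, under ``config.output_dir``: per-layer cutoff-statistics tables,
    the combined GFC table, per-layer and integrated networks (GraphML +
    TSV edge list), the partition and module-summary tables, enrichment
    tables, and ``run_record.json`` with every parameter, seed, library
    version and input digest. Returns the output directory.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = run_analysis(load_state(config), config)

    for lname, st in state.results["cutoff_statistics"].items():
        st.write_tsv(out / f"cutoff_stats_{lname}.tsv")
    write_gfc(state.results["gfc"], out / "gfc.tsv")
    partition = state.results["partition"]
    for lname, net in state.results["layer_networks"].items():
        write_graphml(net, out / f"network_{lname}.graphml")
        write_edgelist(net, out / f"network_{lname}.edges.tsv")
    integrated = state.results["integrated_network"]
    write_graphml(integrated, out / "network_integrated.graphml", partition=partition)
    write_edgelist(integrated, out / "network_integrated.edges.tsv")
    partition.write_tsv(out / "partition.tsv")
    state.results["module_summary"].write_tsv(out / "module_summary.tsv")
    if state.results["enrichments"]:
        for cname, res in state.results["enrichments"].items():
            res["all"].write_tsv(out / f"enrichment_{cname}.tsv")
            res["top"].write_tsv(out / f"enrichment_{cname}_top.tsv")

    record = {
        "package": {"name": "coexnet", "version": __version__},
        "versions": _library_versions(),
        "config": config.to_dict(),
        "chosen_cutoffs": state.parameters["chosen_cutoffs"],
        "input_digests": {
            lconf.name: {
                "expression_sha256": _sha256(lconf.expression),
                "annotation_sha256": _sha256(lconf.annotation),
            }
            for lconf in config.layers
        },
        "integrated_network": {
            "origin": integrated.origin,
            "n_nodes": integrated.n_nodes,
            "n_edges": integrated.n_edges,
        },
        "modules": partition.sizes(),
        "n_unassigned": len(partition.unassigned),
    }
    with open(out / "run_record.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
    return out


def _library_versions() -> dict[str, str]:
    import igraph
    import leidenalg
    import networkx
    import scipy
    import sklearn

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
        "igraph": igraph.__version__,
        "leidenalg": leidenalg.version,
        "scikit-learn": sklearn.__version__,
    }


# ---------------------------------------------------------------------------
# Satellites
# ---------------------------------------------------------------------------

SATELLITES = ("suggest_topvar", "hub_genes", "pca_table", "expression_distributions")


def _require(state: AnalysisState, slot: str, stage: str):
    value = state.results.get(slot)
    if value is None:
        raise ValidationError(
            f"satellite dependency not met: run the {stage!r} stage first "
            f"(result slot {slot!r} is empty)"
        )
    return value


def run_satellite(
    name: str, state: AnalysisState, params: Optional[dict] = None, output_dir=None
):
    """Run one satellite function against the current analysis state.

    Satellites run independently and in any order, but each declares the
    main-analysis stages it depends on and errors (naming the missing
    stage) when run too early. When ``output_dir`` is given, the artifact
    is also written there as a TSV/JSON file.
    """
    params = dict(params or {})
    if name not in SATELLITES:
        raise ValidationError(f"unknown satellite {name!r}; choose from {SATELLITES}")

    if name == "suggest_topvar":
        layer_name = params.get("layer", state.layer_names[0])
        layer, _ = state.layer(layer_name)
        suggestion = suggest_topvar(rank_variances(layer))
        artifact = {"layer": layer_name, "suggested_top_variant": suggestion}
        if output_dir is not None:
            with open(Path(output_dir) / f"suggest_topvar_{layer_name}.json", "w") as fh:
                json.dump(artifact, fh, indent=2)
        return artifact

    if name == "hub_genes":
        partition = _require(state, "partition", "clustering")
        network = _require(state, "integrated_network", "integration")
        module = params.get("module") or partition.labels[0]
        table = hub_genes(
            network,
            partition,
            module,
            k=params.get("k", 10),
            score=params.get("score", "weighted_degree"),
        )
        if output_dir is not None:
            table.to_csv(Path(output_dir) / f"hub_genes_{module}.tsv", sep="\t", index=False)
        return table

    if name == "pca_table":
        from sklearn.decomposition import PCA

        layer_name = params.get("layer", state.layer_names[0])
        layer, _ = state.layer(layer_name)
        n_comp = min(
            int(params.get("n_components", 10)), layer.n_samples - 1, layer.n_genes
        )
        n_comp = max(n_comp, 2)
        X = layer.values.to_numpy().T  # samples x genes
        scores = PCA(n_components=n_comp, random_state=0).fit_transform(
            X - X.mean(axis=0)
        )
        table = pd.DataFrame(
            scores,
            index=layer.samples,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        )
        table.index.name = "sample"
        if output_dir is not None:
            table.to_csv(Path(output_dir) / f"pca_{layer_name}.tsv", sep="\t")
        return table

    # expression_distributions: per-sample location/spread summary
    rows = []
    for layer, _ in state.layers:
        q = layer.values.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        for s in layer.samples:
            rows.append(
                {
                    "layer": layer.name,
                    "sample": s,
                    "min": q.loc[0.0, s],
                    "q25": q.loc[0.25, s],
                    "median": q.loc[0.5, s],
                    "q75": q.loc[0.75, s],
                    "max": q.loc[1.0, s],
                    "mean": layer.values[s].mean(),
                }
            )
    table = pd.DataFrame(rows)
    if output_dir is not None:
        table.to_csv(Path(output_dir) / "expression_distributions.tsv", sep="\t", index=False)
    return table
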