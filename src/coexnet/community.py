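"""Module detection, size filtering, GFC summaries and hub genes.

Communities ("modules") in the integrated network are found by weighted
community detection — Leiden by default (modularity objective, fixed seed),
with Louvain, fast-greedy and edge-betweenness as alternatives. Modules
smaller than a minimum size (default 25 genes) are dissolved and their
genes moved to the unassigned pool. Retained modules are labelled with
color names assigned by descending module size, following the co-expression
field's convention, and are summarized by their mean GFC per layer and
condition group so that conditions can be compared on the module level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .gfc import GfcTable
from .io import ValidationError
from .network import CoexpressionNetwork

__all__ = [
    "MODULE_COLORS",
    "ModulePartition",
    "ModuleSummary",
    "detect_modules",
    "filter_min_size",
    "module_summary",
    "order_conditions",
    "hub_genes",
    "ALGORITHMS",
    "HUB_SCORES",
]

# Fixed color vocabulary for module labels, assigned by descending module
# size; overflow modules fall back to "module_<k>".
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "plum", "orangered", "mediumpurple", "lightsteelblue",
    "lightblue", "gold", "wheat", "orchid", "ivory", "maroon",
)

ALGORITHMS = ("leiden", "louvain", "fast_greedy", "edge_betweenness")
HUB_SCORES = ("weighted_degree", "degree", "betweenness")


@dataclass
class ModulePartition:
    """Assignment of network genes to labelled modules plus an unassigned pool.

    Labels are color names ordered by descending module size (ties broken by
    the lexicographically smallest member gene), so the label sequence is a
    pure function of the partition structure.
    """

    assignment: dict[str, str]
    unassigned: set[str] = field(default_factory=set)
    algorithm: str = "leiden"
    resolution: float = 1.0
    seed: int = 1
    min_size: Optional[int] = None

    @property
    def labels(self) -> list[str]:
        """Module labels in descending-size order."""
        sizes = self.sizes()
        return sorted(sizes, key=lambda m: (-sizes[m], self._anchor(m)))

    def _anchor(self, label: str) -> str:
        return min(g for g, m in self.assignment.items() if m == label)

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, m in self.assignment.items():
            out.setdefault(m, []).append(g)
        return {m: sorted(gs) for m, gs in sorted(out.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))}

    def sizes(self) -> dict[str, int]:
        return {m: len(gs) for m, gs in self.modules().items()}

    def genes(self, label: str) -> list[str]:
        mods = self.modules()
        if label not in mods:
            raise ValidationError(
                f"unknown module {label!r}; available: {list(mods)}"
            )
        return mods[label]

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, m) for g, m in self.assignment.items()]
        rows += [(g, "unassigned") for g in self.unassigned]
        df = pd.DataFrame(rows, columns=["gene", "module"])
        return df.sort_values("gene", kind="mergesort").reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _label_communities(communities: list[list[str]]) -> dict[str, str]:
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment: dict[str, str] = {}
    for k, comm in enumerate(ordered):
        label = MODULE_COLORS[k] if k < len(MODULE_COLORS) else f"module_{k + 1}"
        for g in comm:
            assignment[g] = label
    return assignment


def _to_igraph(network: CoexpressionNetwork) -> tuple[ig.Graph, list[str]]:
    genes = sorted(network.graph.nodes)
    index = {g: i for i, g in enumerate(genes)}
    edges, weights = [], []
    for u, v, data in network.graph.edges(data=True):
        edges.append((index[u], index[v]))
        weights.append(float(data["weight"]))
    g = ig.Graph(n=len(genes), edges=edges)
    g.es["weight"] = weights
    return g, genes


def detect_modules(
    network: CoexpressionNetwork,
    algorithm: str = "leiden",
    resolution: float = 1.0,
    seed: int = 1,
) -> ModulePartition:
    """Partition the network's genes into co-expression modules.

    All algorithms use edge weights in their objective. Leiden and Louvain
    optimize (resolution-parametrized) weighted modularity and are
    deterministic under a fixed seed; fast-greedy and edge-betweenness are
    deterministic classics that ignore the resolution parameter.
    """
    if algorithm not in ALGORITHMS:
        raise ValidationError(
            f"unknown clustering algorithm {algorithm!r}; choose from {ALGORITHMS}"
        )
    if network.n_nodes == 0:
        raise ValidationError("cannot cluster an empty network")

    if algorithm == "louvain":
        comms = nx.community.louvain_communities(
            network.graph, weight="weight", resolution=resolution, seed=seed
        )
        communities = [sorted(c) for c in comms]
    else:
        g, genes = _to_igraph(network)
        if algorithm == "leiden":
            part = leidenalg.find_partition(
                g,
                leidenalg.RBConfigurationVertexPartition,
                weights="weight",
                resolution_parameter=resolution,
                seed=seed,
                n_iterations=-1,  # iterate to convergence
            )
            membership = part.membership
        elif algorithm == "fast_greedy":
            membership = g.community_fastgreedy(weights="weight").as_clustering().membership
        else:  # edge_betweenness
            membership = g.community_edge_betweenness(weights="weight").as_clustering().membership
        comm_map: dict[int, list[str]] = {}
        for gene, m in zip(genes, membership):
            comm_map.setdefault(m, []).append(gene)
        communities = list(comm_map.values())

    return ModulePartition(
        assignment=_label_communities(communities),
        unassigned=set(),
        algorithm=algorithm,
        resolution=resolution,
        seed=seed,
    )


def filter_min_size(partition: ModulePartition, min_size: int = 25) -> ModulePartition:
    """Dissolve modules below ``min_size``; their genes become unassigned.

    Surviving modules are relabelled by descending size so labels stay a
    pure function of the retained structure.
    """
    if min_size < 1:
        raise ValidationError(f"min_size must be >= 1, got {min_size}")
    keep, dropped = [], set(partition.unassigned)
    for label, genes in partition.modules().items():
        if len(genes) >= min_size:
            keep.append(genes)
        else:
            dropped.update(genes)
    return ModulePartition(
        assignment=_label_communities(keep),
        unassigned=dropped,
        algorithm=partition.algorithm,
        resolution=partition.resolution,
        seed=partition.seed,
        min_size=min_size,
    )


# ---------------------------------------------------------------------------
# Module summaries
# ---------------------------------------------------------------------------


@dataclass
class ModuleSummary:
    """Module-by-(layer, group) mean-GFC matrix plus module sizes.

    Each cell is the arithmetic mean of the *defined* GFCs of the module's
    genes for that layer and group; genes not measured in a layer (or with
    undefined GFC) contribute nothing to that layer's cells. A cell with no
    defined GFC at all is NaN.
    """

    table: pd.DataFrame  # index: modules; columns: MultiIndex (layer, group)
    sizes: dict[str, int]
    column_order: Optional[list[tuple[str, str]]] = None
    linkage: Optional[np.ndarray] = None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for module in self.table.index:
            for layer, group in self.table.columns:
                rows.append(
                    {
                        "module": module,
                        "layer": layer,
                        "group": group,
                        "mean_gfc": self.table.loc[module, (layer, group)],
                        "size": self.sizes[module],
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def module_summary(partition: ModulePartition, gfcs: Sequence[GfcTable]) -> ModuleSummary:
    """Mean GFC per module, layer and condition group."""
    modules = partition.modules()
    if not modules:
        raise ValidationError("partition has no modules to summarize")
    columns = [(tab.layer_name, grp) for tab in gfcs for grp in tab.groups]
    data = {}
    for tab in gfcs:
        for label, genes in modules.items():
            present = [g for g in genes if g in tab.values.index]
            for grp in tab.groups:
                cell = np.nan
                if present:
                    vals = tab.values.loc[present, grp].dropna()
                    if len(vals):
                        cell = float(vals.mean())
                data.setdefault(label, {})[(tab.layer_name, grp)] = cell
    table = pd.DataFrame.from_dict(data, orient="index")
    table = table.loc[list(modules), pd.MultiIndex.from_tuples(columns)]
    return ModuleSummary(table=table, sizes={m: len(g) for m, g in modules.items()})


def _pairwise_complete_euclidean(M: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distance over columns, rescaling by the shared
    (non-NaN) dimension count when cells are missing."""
    n = M.shape[1]
    out = []
    p = M.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(M[:, i]) & np.isfinite(M[:, j])
            if not mask.any():
                raise ValidationError(
                    "two condition columns share no defined module GFCs; "
                    "cannot compute a distance"
                )
            d2 = np.sum((M[mask, i] - M[mask, j]) ** 2) * (p / mask.sum())
            out.append(np.sqrt(d2))
    return np.asarray(out)


def order_conditions(
    summary: ModuleSummary, method: str = "complete"
) -> ModuleSummary:
    """Hierarchically cluster the (layer, group) columns of a module summary.

    Agglomerative clustering on Euclidean distance between the columns'
    mean-GFC profiles (default: complete linkage). Undefined cells trigger a
    pairwise-complete distance with a warning. Returns a new summary with
    ``column_order`` (deterministic leaf order) and the linkage matrix set.
    """
    M = summary.table.to_numpy(dtype=float)
    cols = list(summary.table.columns)
    if len(cols) < 2:
        raise ValidationError("need at least 2 condition columns to order")
    if np.isnan(M).any():
        warnings.warn(
            "undefined mean-GFC cells present; using pairwise-complete distances",
            stacklevel=2,
        )
        condensed = _pairwise_complete_euclidean(M)
    else:
        condensed = pdist(M.T, metric="euclidean")
    Z = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(Z)
    return ModuleSummary(
        table=summary.table,
        sizes=summary.sizes,
        column_order=[cols[i] for i in order],
        linkage=Z,
    )


# ---------------------------------------------------------------------------
# Hub genes
# ---------------------------------------------------------------------------


def hub_genes(
    network: CoexpressionNetwork,
    partition: ModulePartition,
    module: str,
    k: int = 10,
    score: str = "weighted_degree",
) -> pd.DataFrame:
    """Top-``k`` hub genes of a module's induced subgraph.

    The default hub score is the weighted degree (sum of incident edge
    weights) within the module-induced subgraph; ``degree`` and
    ``betweenness`` are exposed as alternatives. Ties are broken by
    lexicographic gene identifier, so rankings are stable across reruns.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if score not in HUB_SCORES:
        raise ValidationError(f"unknown hub score {score!r}; choose from {HUB_SCORES}")
    genes = partition.genes(module)
    sub = network.graph.subgraph([g for g in genes if g in network.graph])
    if score == "weighted_degree":
        scores = {g: float(d) for g, d in sub.degree(weight="weight")}
    elif score == "degree":
        scores = {g: float(d) for g, d in sub.degree()}
    else:
        scores = {g: float(s) for g, s in nx.betweenness_centrality(sub, weight=None).items()}
    for g in genes:
        scores.setdefault(g, 0.0)
    ranked = sorted(scores, key=lambda g: (-scores[g], g))[:k]
    return pd.DataFrame(
        {"gene": ranked, "score": [scores[g] for g in ranked], "module": module}
    )
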