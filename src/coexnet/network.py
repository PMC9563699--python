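"""Co-expression network construction and horizontal integration.

Each layer's correlation matrix is thresholded into an undirected weighted
graph (edge weight = correlation coefficient, threshold inclusive, positive
coefficients only). Layer networks are then combined either by **union**
(every node and edge from any layer; the holistic view) or by
**intersection** (one layer's network serves as the reference; edges are
annotated with their presence and weight in every other layer).

An edge present in several layers is a multi-edge; its integrated weight is
resolved by a policy — ``min`` (default, the conservative lower bound on
the true co-expression, which also thins the network for clustering),
``mean`` or ``max`` — computed over the layers that actually contain the
edge (absence is structural, never treated as weight zero). Full per-layer
provenance is kept on every integrated edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ValidationError
from .preprocess import CorrelationResult

__all__ = [
    "CoexpressionNetwork",
    "build_network",
    "integrate_union",
    "integrate_intersection",
    "resolve_multiedge",
    "write_graphml",
    "read_graphml",
    "write_edgelist",
    "POLICIES",
]

POLICIES = ("min", "mean", "max")


def resolve_multiedge(weights: dict[str, float], policy: str = "min") -> float:
    """Collapse per-layer edge weights to one integrated weight."""
    if not weights:
        raise ValidationError("cannot resolve an edge with no layer weights")
    if policy not in POLICIES:
        raise ValidationError(f"unknown multi-edge policy {policy!r}; choose from {POLICIES}")
    vals = list(weights.values())
    if policy == "min":
        return float(min(vals))
    if policy == "max":
        return float(max(vals))
    return float(sum(vals) / len(vals))


@dataclass
class CoexpressionNetwork:
    """Undirected weighted gene graph with per-layer edge provenance.

    ``graph`` is a :class:`networkx.Graph`; every edge carries ``weight``
    (the resolved weight, in (0, 1]) and ``layer_weights`` (mapping layer
    name to that layer's original coefficient). ``origin`` records whether
    this is a single-layer network or a union/intersection integration.
    Isolated genes are never members: every node has degree >= 1 (an empty
    network is a valid degenerate object).
    """

    graph: nx.Graph
    origin: str = "single_layer"
    name: str = ""
    layer_names: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def edge_weight(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["weight"])

    def provenance(self, u: str, v: str) -> dict[str, float]:
        return dict(self.graph.edges[u, v]["layer_weights"])


def build_network(
    corr: CorrelationResult, cutoff: float, name: Optional[str] = None
) -> CoexpressionNetwork:
    """Threshold a correlation matrix into a single-layer network.

    Edges are pairs with signed coefficient >= ``cutoff`` (inclusive);
    genes left without any edge are dropped. An empty result is valid but
    warned about.
    """
    if not 0 < cutoff <= 1:
        raise ValidationError(f"cutoff must lie in (0, 1], got {cutoff}")
    layer = name or corr.layer_name or "layer"
    G = nx.Graph()
    C = corr.matrix
    genes = corr.genes
    with np.errstate(invalid="ignore"):
        ii, jj = np.where(np.triu(C >= cutoff, k=1))
    for i, j in zip(ii, jj):
        w = float(C[i, j])
        G.add_edge(genes[i], genes[j], weight=w, layer_weights={layer: w})
    if G.number_of_edges() == 0:
        warnings.warn(
            f"layer {layer!r}: no gene pair reaches cutoff {cutoff}; "
            "network is empty",
            stacklevel=2,
        )
    return CoexpressionNetwork(
        graph=G, origin="single_layer", name=layer, layer_names=[layer]
    )


def _merged_layer_names(networks: Sequence[CoexpressionNetwork]) -> list[str]:
    names: list[str] = []
    for net in networks:
        for n in net.layer_names or [net.name]:
            if n not in names:
                names.append(n)
    return names


def integrate_union(
    networks: Sequence[CoexpressionNetwork], policy: str = "min"
) -> CoexpressionNetwork:
    """Union of layer networks with policy-resolved multi-edge weights.

    The node set is the union of node sets and the edge set the union of
    edge sets, so co-expression unique to one layer is retained. Shared
    edges keep full per-layer provenance; their integrated weight is the
    policy statistic over the layers containing the edge.
    """
    networks = list(networks)
    if not networks:
        raise ValidationError("integration requires at least one network")
    if policy not in POLICIES:
        raise ValidationError(f"unknown multi-edge policy {policy!r}; choose from {POLICIES}")
    G = nx.Graph()
    for net in networks:
        for u, v, data in net.graph.edges(data=True):
            prov = dict(data["layer_weights"])
            if G.has_edge(u, v):
                G.edges[u, v]["layer_weights"].update(prov)
            else:
                G.add_edge(u, v, layer_weights=prov)
    for u, v in G.edges:
        G.edges[u, v]["weight"] = resolve_multiedge(G.edges[u, v]["layer_weights"], policy)
    return CoexpressionNetwork(
        graph=G,
        origin="union",
        name="union(" + ",".join(_merged_layer_names(networks)) + ")",
        layer_names=_merged_layer_names(networks),
    )


def integrate_intersection(
    networks: Sequence[CoexpressionNetwork], reference: str, policy: str = "min"
) -> CoexpressionNetwork:
    """Reference-anchored integration: keep the reference network's topology.

    The result's node and edge sets equal the reference's; every edge is
    annotated with its weight in each other layer where present (absent
    layers simply do not appear in the provenance). The integrated weight
    is re-resolved by ``policy`` over the layers containing the edge, and
    the reference's own weight is kept as ``reference_weight``.
    """
    networks = list(networks)
    if not networks:
        raise ValidationError("integration requires at least one network")
    if policy not in POLICIES:
        raise ValidationError(f"unknown multi-edge policy {policy!r}; choose from {POLICIES}")
    by_name = {net.name: net for net in networks}
    if reference not in by_name:
        raise ValidationError(
            f"unknown reference network {reference!r}; available: {sorted(by_name)}"
        )
    ref = by_name[reference]
    others = [net for net in networks if net.name != reference]
    G = nx.Graph()
    for u, v, data in ref.graph.edges(data=True):
        prov = dict(data["layer_weights"])
        for net in others:
            if net.graph.has_edge(u, v):
                prov.update(net.graph.edges[u, v]["layer_weights"])
        G.add_edge(
            u,
            v,
            layer_weights=prov,
            weight=resolve_multiedge(prov, policy),
            reference_weight=float(data["weight"]),
        )
    G.add_nodes_from(ref.graph.nodes)
    return CoexpressionNetwork(
        graph=G,
        origin="intersection",
        name=f"intersection(ref={reference})",
        layer_names=_merged_layer_names(networks),
    )


# ---------------------------------------------------------------------------
# Export (Cytoscape-compatible)
# ---------------------------------------------------------------------------


def write_graphml(network: CoexpressionNetwork, path, partition=None) -> None:
    """GraphML export: per-edge resolved weight plus one attribute per layer
    weight; optional node ``module`` attribute from a partition."""
    H = nx.Graph()
    for n in sorted(network.graph.nodes):
        attrs = {}
        if partition is not None:
            attrs["module"] = partition.assignment.get(n, "unassigned")
        H.add_node(n, **attrs)
    for u, v, data in network.graph.edges(data=True):
        attrs = {"weight": float(data["weight"])}
        for layer, w in sorted(data["layer_weights"].items()):
            attrs[f"weight_{layer}"] = float(w)
        H.add_edge(u, v, **attrs)
    nx.write_graphml(H, path)


def read_graphml(path) -> CoexpressionNetwork:
    """Read back a GraphML export, reconstructing per-layer provenance."""
    H = nx.read_graphml(path)
    G = nx.Graph()
    G.add_nodes_from(H.nodes)
    layers: list[str] = []
    for u, v, data in H.edges(data=True):
        prov = {
            k[len("weight_"):]: float(w)
            for k, w in data.items()
            if k.startswith("weight_")
        }
        for lay in prov:
            if lay not in layers:
                layers.append(lay)
        G.add_edge(u, v, weight=float(data["weight"]), layer_weights=prov)
    return CoexpressionNetwork(graph=G, origin="imported", layer_names=sorted(layers))


def write_edgelist(network: CoexpressionNetwork, path) -> None:
    """Tab-separated edge list (gene1, gene2, weight, one column per layer)
    suitable for Cytoscape import; absent layers are written as NA."""
    layers = network.layer_names or sorted(
        {lay for _, _, d in network.graph.edges(data=True) for lay in d["layer_weights"]}
    )
    rows = []
    for u, v, data in sorted(
        network.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
    ):
        a, b = sorted((u, v))
        row = {"gene1": a, "gene2": b, "weight": data["weight"]}
        for lay in layers:
            row[f"weight_{lay}"] = data["layer_weights"].get(lay, np.nan)
        rows.append(row)
    cols = ["gene1", "gene2", "weight"] + [f"weight_{lay}" for lay in layers]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, na_rep="NA")
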