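"""Module-level over-representation analysis.

Each module is tested against every set of a GMT collection with the
one-sided hypergeometric upper-tail test: with a universe of ``M`` genes of
which ``K`` belong to the set and a module of ``n`` universe genes showing
``k`` in the set, p = P(X >= k) for X ~ Hypergeometric(M, K, n). Module and
sets are intersected with the universe before testing; the universe
defaults, at the pipeline level, to the genes of the integrated network
(the object being interpreted).

Raw p-values are Benjamini-Hochberg adjusted per module across the sets of
one collection, and results are typically filtered to the top 5 terms with
adjusted p <= 0.1 per module. Transcription-factor target enrichment runs
the identical machinery on TF-target GMT libraries, additionally reporting
which target pairs are connected in the integrated network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import ModulePartition
from .io import GeneSetCollection, ValidationError
from .network import CoexpressionNetwork

__all__ = [
    "EnrichmentResult",
    "over_representation",
    "enrich_modules",
    "adjust_bh",
    "top_terms",
    "tf_enrichment",
]

_COLUMNS = [
    "module",
    "set_name",
    "overlap",
    "module_size",
    "set_size",
    "universe_size",
    "p_value",
    "adjusted_p",
]


@dataclass
class EnrichmentResult:
    """Per-module, per-set over-representation rows.

    ``frame`` columns: module, set_name, overlap, module_size (module genes
    in the universe), set_size (set genes in the universe), universe_size,
    p_value, adjusted_p.
    """

    frame: pd.DataFrame
    collection: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"enrichment frame missing columns {missing}")

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _hypergeom_upper(k: int, M: int, K: int, n: int) -> float:
    """P(overlap >= k) for a draw of n from a universe of M with K marked."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def over_representation(
    module_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    module_label: str = "module",
) -> EnrichmentResult:
    """Hypergeometric over-representation of one gene set collection in one module."""
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    module = frozenset(module_genes) & universe
    if not module:
        warnings.warn(
            f"module {module_label!r} shares no genes with the universe; "
            "all overlaps are 0 and p-values 1",
            stacklevel=2,
        )
    M = len(universe)
    rows = []
    for name in collection.sets:
        in_universe = collection.as_set(name) & universe
        overlap = len(module & in_universe)
        rows.append(
            {
                "module": module_label,
                "set_name": name,
                "overlap": overlap,
                "module_size": len(module),
                "set_size": len(in_universe),
                "universe_size": M,
                "p_value": _hypergeom_upper(overlap, M, len(in_universe), len(module)),
            }
        )
    frame = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    frame["adjusted_p"] = adjust_bh(frame["p_value"]) if len(frame) else []
    return EnrichmentResult(frame=frame, collection=collection.source)


def enrich_modules(
    partition: ModulePartition,
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> EnrichmentResult:
    """Over-representation of a collection in every retained module.

    BH adjustment is applied per module across the collection's sets
    (matching top-terms-per-module reporting).
    """
    universe = frozenset(universe)
    frames = [
        over_representation(genes, collection, universe, module_label=label).frame
        for label, genes in partition.modules().items()
    ]
    frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_COLUMNS)
    )
    return EnrichmentResult(frame=frame, collection=collection.source)


def top_terms(result: EnrichmentResult, n: int = 5, alpha: float = 0.1) -> EnrichmentResult:
    """Per module: rows with adjusted p <= ``alpha``, then the ``n`` smallest.

    Ties at the boundary rank go to the smaller raw p-value, then to the
    lexicographically smaller set name. Modules with nothing passing
    contribute zero rows.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    frame = result.frame
    kept = frame[frame["adjusted_p"] <= alpha]
    kept = kept.sort_values(
        ["module", "adjusted_p", "p_value", "set_name"], kind="mergesort"
    )
    out = kept.groupby("module", sort=False, group_keys=False).head(n)
    return EnrichmentResult(frame=out.reset_index(drop=True), collection=result.collection)


def tf_enrichment(
    partition: ModulePartition,
    tf_targets: GeneSetCollection,
    universe: Iterable[str],
    network: Optional[CoexpressionNetwork] = None,
) -> EnrichmentResult:
    """Transcription-factor target over-representation per module.

    Identical test machinery to :func:`over_representation`, run on a
    TF-target collection (sets keyed by TF name). TFs with no target in the
    universe are dropped with a warning. When the integrated network is
    supplied, each row additionally lists which pairs of the module's
    target genes are connected by a network edge (``target_edges``,
    semicolon-separated ``a|b`` pairs).
    """
    universe = frozenset(universe)
    usable = {
        tf: genes
        for tf, genes in tf_targets.sets.items()
        if set(genes) & universe
    }
    dropped = sorted(set(tf_targets.sets) - set(usable))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} TF(s) with no target in the universe: "
            f"{dropped}",
            stacklevel=2,
        )
    if not usable:
        return EnrichmentResult(
            frame=pd.DataFrame(columns=_COLUMNS + (["target_edges"] if network else [])),
            collection=tf_targets.source,
        )
    collection = GeneSetCollection(sets=usable, source=tf_targets.source)
    result = enrich_modules(partition, collection, universe)
    if network is not None:
        modules = partition.modules()
        edges = []
        for _, row in result.frame.iterrows():
            targets = sorted(
                set(collection.as_set(row["set_name"]))
                & set(modules[row["module"]])
            )
            connected = [
                f"{a}|{b}"
                for i, a in enumerate(targets)
                for b in targets[i + 1:]
                if network.graph.has_edge(a, b)
            ]
            edges.append(";".join(connected))
        result.frame["target_edges"] = edges
    return result
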