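"""Per-layer preprocessing: variance filtering, pairwise correlation, and
cut-off statistics.

The pre-integration stage reduces each layer to its most variant genes,
computes all pairwise gene-gene correlations, and tabulates, for a grid of
candidate correlation cut-offs, the size and scale-free-topology quality of
the network each cut-off would produce. The cut-off choice itself is left to
the user (or config); :func:`suggest_cutoff` provides a clearly-labeled
heuristic default.

Edges are formed from the *signed* coefficient (positive co-expression
only) and the threshold is inclusive: a pair at exactly the cut-off keeps
its edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import ExpressionLayer, ValidationError

__all__ = [
    "VarianceCurve",
    "CorrelationResult",
    "CutoffStatistics",
    "rank_variances",
    "suggest_topvar",
    "inflection_ranks",
    "filter_top_variant",
    "compute_correlations",
    "correlation_from_matrix",
    "cutoff_statistics",
    "degree_distribution_r2",
    "suggest_cutoff",
    "default_cutoff_grid",
]


# ---------------------------------------------------------------------------
# Variance ranking and filtering
# ---------------------------------------------------------------------------


@dataclass
class VarianceCurve:
    """Genes ranked by descending expression variance.

    ``genes``/``variances`` cover all genes (zero-variance genes last);
    ``log_variance`` is log10 variance over the positive-variance prefix
    only, hence non-increasing in rank.
    """

    genes: list[str]
    variances: np.ndarray
    zero_variance_genes: list[str]

    @property
    def log_variance(self) -> np.ndarray:
        pos = self.variances[self.variances > 0]
        return np.log10(pos)

    def __len__(self) -> int:
        return len(self.genes)


def rank_variances(layer: ExpressionLayer) -> VarianceCurve:
    """Rank genes by descending variance across samples.

    Ties are broken by lexicographic gene identifier; genes with zero
    variance are placed last and flagged. An all-constant matrix is an
    error — there is nothing to rank.
    """
    var = layer.values.var(axis=1, ddof=1)
    if (var == 0).all():
        raise ValidationError(
            f"layer {layer.name!r}: all genes constant, nothing to rank"
        )
    order = sorted(layer.genes, key=lambda g: (-var[g], g))
    variances = np.array([var[g] for g in order])
    zero = [g for g in order if var[g] == 0]
    return VarianceCurve(genes=order, variances=variances, zero_variance_genes=zero)


def _second_differences(curve: VarianceCurve, window: Optional[int]) -> tuple[np.ndarray, int, int]:
    """Curvature of the smoothed log-variance curve.

    Returns ``(d2, window, offset)`` where ``d2[i]`` is the discrete second
    difference at 1-based rank ``i + offset``. Smoothing is a centered
    moving average restricted to ranks with a complete window, so an
    exactly linear curve yields exactly zero curvature (no edge artefacts).
    """
    y = curve.log_variance
    m = len(y)
    if window is None:
        window = max(5, int(round(0.01 * m)))
    if window % 2 == 0:
        window += 1
    half = window // 2
    if m < window + 2:
        return np.array([]), window, 0
    ys = np.convolve(y, np.ones(window) / window, mode="valid")  # ranks half+1..m-half
    d2 = ys[2:] - 2.0 * ys[1:-1] + ys[:-2]
    return d2, window, half + 2  # d2[0] sits at 1-based rank half+2

# curvature below this (relative to the curve's dynamic range) is treated as flat
_FLAT_TOL = 1e-9


def inflection_ranks(curve: VarianceCurve, window: Optional[int] = None) -> list[int]:
    """1-based ranks of all local maxima of curvature magnitude.

    Curvature is the discrete second difference of the smoothed ranked
    log-variance curve; ranks are returned in ascending order.
    """
    d2, _, offset = _second_differences(curve, window)
    if d2.size == 0:
        return []
    mag = np.abs(d2)
    scale = max(np.ptp(curve.log_variance), 1.0)
    ranks = []
    for i in range(mag.size):
        left = mag[i - 1] if i > 0 else -np.inf
        right = mag[i + 1] if i < mag.size - 1 else -np.inf
        if mag[i] > _FLAT_TOL * scale and mag[i] >= left and mag[i] >= right:
            ranks.append(i + offset)
    return ranks


def suggest_topvar(curve: VarianceCurve, window: Optional[int] = None) -> int:
    """Suggest a top-variant gene count from the ranked log-variance curve.

    Returns the 1-based rank at which the smoothed curve has maximal
    curvature magnitude (its strongest inflection). Degenerate curves — too
    short for the smoothing window, or with no detectable inflection (e.g.
    exactly linear in log variance) — fall back to the full gene count with
    a warning.
    """
    d2, window, offset = _second_differences(curve, window)
    n = len(curve)
    if d2.size == 0:
        warnings.warn(
            f"variance curve shorter than smoothing window ({window}); "
            "falling back to the full gene count",
            stacklevel=2,
        )
        return n
    mag = np.abs(d2)
    scale = max(np.ptp(curve.log_variance), 1.0)
    if mag.max() <= _FLAT_TOL * scale:
        warnings.warn(
            "no inflection detected in the ranked log-variance curve; "
            "falling back to the full gene count",
            stacklevel=2,
        )
        return n
    return int(np.argmax(mag)) + offset


def filter_top_variant(layer: ExpressionLayer, n: Optional[int]) -> ExpressionLayer:
    """Keep the ``n`` highest-variance genes (ties: lower gene ID kept).

    ``n = None`` (or the total gene count) skips filtering and returns an
    identical layer.
    """
    if n is None or n == layer.n_genes:
        return ExpressionLayer(name=layer.name, values=layer.values.copy())
    if not 1 <= n <= layer.n_genes:
        raise ValidationError(
            f"top-variant count {n} out of range [1, {layer.n_genes}] "
            f"for layer {layer.name!r}"
        )
    curve = rank_variances(layer)
    keep = curve.genes[:n]
    return ExpressionLayer(name=layer.name, values=layer.values.loc[keep])


# ---------------------------------------------------------------------------
# Pairwise correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Symmetric pairwise gene-gene correlations for one layer.

    ``matrix`` is gene-by-gene with NaN on the diagonal (self-pairs are
    excluded) and NaN for any pair involving a constant gene (correlation
    undefined, excluded from networks).
    """

    genes: list[str]
    method: str
    matrix: np.ndarray
    layer_name: str = ""
    constant_genes: list[str] = field(default_factory=list)

    def pair(self, a: str, b: str) -> float:
        i, j = self.genes.index(a), self.genes.index(b)
        return float(self.matrix[i, j])


def compute_correlations(layer: ExpressionLayer, method: str = "spearman") -> CorrelationResult:
    """All pairwise gene correlations (Pearson or Spearman) in one layer.

    Spearman uses average ranks for ties. Constant genes yield NaN against
    every partner. Requires at least 2 samples (3+ recommended for a
    meaningful coefficient).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if layer.n_samples < 2:
        raise ValidationError(
            f"layer {layer.name!r}: need >=2 samples for correlation"
        )
    X = layer.values.to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)  # average-rank ties
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    const = norm == 0
    safe = np.where(const, 1.0, norm)
    Z = Xc / safe[:, None]
    C = np.clip(Z @ Z.T, -1.0, 1.0)
    C[const, :] = np.nan
    C[:, const] = np.nan
    np.fill_diagonal(C, np.nan)
    return CorrelationResult(
        genes=layer.genes,
        method=method,
        matrix=C,
        layer_name=layer.name,
        constant_genes=[g for g, c in zip(layer.genes, const) if c],
    )


def correlation_from_matrix(
    genes: Sequence[str], matrix: np.ndarray, layer_name: str = ""
) -> CorrelationResult:
    """Wrap a precomputed symmetric coefficient matrix (e.g. from another tool)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(genes), len(genes)):
        raise ValidationError("precomputed matrix shape does not match gene list")
    with np.errstate(invalid="ignore"):
        if np.nanmax(np.abs(matrix)) > 1 + 1e-12:
            raise ValidationError("correlation coefficients must lie in [-1, 1]")
        if not np.allclose(matrix, matrix.T, equal_nan=True):
            raise ValidationError("precomputed matrix must be symmetric")
    M = matrix.copy()
    np.fill_diagonal(M, np.nan)
    return CorrelationResult(
        genes=list(genes), method="precomputed", matrix=M, layer_name=layer_name
    )


# ---------------------------------------------------------------------------
# Cut-off statistics
# ---------------------------------------------------------------------------


def default_cutoff_grid(low: float = 0.9, high: float = 1.0, n: int = 50) -> np.ndarray:
    """Candidate edge thresholds: 50 evenly spaced values in [0.9, 1.0]."""
    return np.linspace(low, high, n)


@dataclass
class CutoffStatistics:
    """Network criteria per candidate cut-off: scale-free R², edge count,
    node count, and number of connected components."""

    cutoffs: np.ndarray
    r_squared: np.ndarray  # NaN where undefined (<2 distinct degrees)
    n_edges: np.ndarray
    n_nodes: np.ndarray
    n_components: np.ndarray
    layer_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "r_squared": self.r_squared,
                "n_edges": self.n_edges,
                "n_nodes": self.n_nodes,
                "n_components": self.n_components,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def degree_distribution_r2(degrees: Sequence[int]) -> float:
    """Scale-free topology score of a degree sequence.

    Least-squares fit of log10(frequency) on log10(degree) over the
    *distinct* positive degrees (isolated nodes excluded); returns the
    coefficient of determination, or NaN when fewer than two distinct
    degrees make the fit undefined.
    """
    degrees = np.asarray(list(degrees), dtype=float)
    if degrees.size == 0:
        raise ValidationError("empty degree list")
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        raise ValidationError("need at least one node with degree >= 1")
    distinct, counts = np.unique(degrees, return_counts=True)
    if distinct.size < 2:
        return float("nan")
    x, y = np.log10(distinct), np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # constant log-frequency: the fitted (horizontal) line is exact
        return 1.0
    return 1.0 - ss_res / ss_tot


def cutoff_statistics(
    corr: CorrelationResult, cutoffs: Optional[Sequence[float]] = None
) -> CutoffStatistics:
    """Tabulate network criteria over an ascending cut-off grid.

    For each cut-off the graph of pairs with coefficient >= cut-off is
    formed (isolated genes excluded) and its scale-free R², edge count,
    node count, and component count are recorded. Because thresholded edge
    sets are nested, edge and node counts are non-increasing in the cut-off.
    """
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    if cutoffs.size == 0:
        raise ValidationError("empty cutoff list")
    if np.any(cutoffs <= 0) or np.any(cutoffs > 1):
        raise ValidationError("cutoffs must lie in (0, 1]")
    if np.any(np.diff(cutoffs) <= 0):
        raise ValidationError("cutoffs must be strictly ascending")

    C = corr.matrix
    n = len(corr.genes)
    r2 = np.full(cutoffs.size, np.nan)
    n_edges = np.zeros(cutoffs.size, dtype=int)
    n_nodes = np.zeros(cutoffs.size, dtype=int)
    n_comp = np.zeros(cutoffs.size, dtype=int)
    with np.errstate(invalid="ignore"):
        for k, c in enumerate(cutoffs):
            adj = C >= c  # NaN compares False: constant genes never form edges
            degrees = adj.sum(axis=1)
            keep = degrees > 0
            n_nodes[k] = int(keep.sum())
            n_edges[k] = int(adj[np.triu_indices(n, k=1)].sum())
            if n_nodes[k] == 0:
                n_comp[k] = 0
                continue
            sub = adj[np.ix_(keep, keep)]
            n_comp[k] = connected_components(csr_matrix(sub), directed=False)[0]
            r2[k] = degree_distribution_r2(degrees[keep])
    return CutoffStatistics(
        cutoffs=cutoffs,
        r_squared=r2,
        n_edges=n_edges,
        n_nodes=n_nodes,
        n_components=n_comp,
        layer_name=corr.layer_name,
    )


def suggest_cutoff(statistics: CutoffStatistics, min_node_fraction: float = 0.9) -> float:
    """Heuristic cut-off choice (convenience only — inspect the guide table).

    Among grid cut-offs whose network retains at least ``min_node_fraction``
    of the maximum node count seen anywhere on the grid, pick the one
    maximizing scale-free R²; ties go to the lower cut-off (more genes
    kept). Falls back to the cut-off with the most nodes when R² is
    undefined everywhere in the candidate set.
    """
    nodes = statistics.n_nodes
    if nodes.max() == 0:
        raise ValidationError("no cutoff on the grid yields any edges")
    candidates = np.where(nodes >= min_node_fraction * nodes.max())[0]
    r2 = statistics.r_squared[candidates]
    if np.all(np.isnan(r2)):
        best = candidates[int(np.argmax(nodes[candidates]))]
    else:
        best = candidates[int(np.nanargmax(r2))]
    return float(statistics.cutoffs[best])
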