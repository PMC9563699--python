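"""Input/output and the unified analysis state.

Readers for the three input formats (expression matrices, sample
annotations, GMT gene-set collections), the corresponding writers, and the
:class:`AnalysisState` container that carries parameters and stage results
through the pipeline.

Conventions
-----------
* Expression matrices are delimited text with genes as rows (first column =
  gene identifier) and samples as columns (header row = sample identifiers).
* Annotations are delimited text with samples as rows (first column = sample
  identifier) and metadata categories as columns.
* Gene sets use the standard GMT dialect: tab-separated, field 1 = set name,
  field 2 = description (ignored on read), fields 3+ = member genes.
* Gene and sample identifiers are whitespace-stripped but case-sensitive;
  matching across layers is by exact string.
* Delimiter auto-detection considers tab and comma only; pass ``delimiter``
  explicitly to override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionLayer",
    "AnnotationTable",
    "GeneSetCollection",
    "AnalysisState",
    "RESULT_SLOTS",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "validate_state",
]


class ValidationError(ValueError):
    """Raised when an input file or object violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionLayer:
    """One dataset's normalized gene-by-sample expression matrix.

    Parameters
    ----------
    name
        Layer label used in provenance, GFC tables and integration.
    values
        DataFrame with unique gene identifiers as index and unique sample
        identifiers as columns; all entries finite.
    """

    name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index.astype(str).str.strip()
        cols = self.values.columns.astype(str).str.strip()
        self.values = self.values.copy()
        self.values.index = idx
        self.values.columns = cols
        dup_g = idx[idx.duplicated()].unique().tolist()
        if dup_g:
            raise ValidationError(
                f"layer {self.name!r}: duplicate gene identifiers {dup_g}"
            )
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(
                f"layer {self.name!r}: duplicate sample identifiers {dup_s}"
            )
        # >=1 gene so that derived single-gene layers (e.g. top-1 variance
        # filter) stay representable; file inputs are checked for >=2 genes
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValidationError(
                f"layer {self.name!r}: need at least 1 gene and 2 samples, "
                f"got {self.values.shape[0]} x {self.values.shape[1]}"
            )
        try:
            arr = self.values.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"layer {self.name!r}: non-numeric values in matrix ({exc})"
            ) from None
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))
            g, s = self.values.index[bad[0][0]], self.values.columns[bad[0][1]]
            raise ValidationError(
                f"layer {self.name!r}: non-finite value at gene {g!r}, sample {s!r}"
            )
        self.values = self.values.astype(float)

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class AnnotationTable:
    """Sample metadata for one layer, with a designated grouping column.

    ``grouping_column`` names the categorical column whose distinct labels
    define the condition groups; ``control_label``, when set, marks the
    control group used by the with-control GFC mode.
    """

    table: pd.DataFrame
    grouping_column: str
    control_label: Optional[str] = None

    def __post_init__(self) -> None:
        idx = self.table.index.astype(str).str.strip()
        self.table = self.table.copy()
        self.table.index = idx
        dup = idx[idx.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"annotation: duplicate sample identifiers {dup}")
        if self.grouping_column not in self.table.columns:
            raise ValidationError(
                f"grouping column {self.grouping_column!r} not found; "
                f"available: {list(self.table.columns)}"
            )
        labels = self.table[self.grouping_column].astype(str)
        if labels.isna().any() or (labels.str.strip() == "").any():
            raise ValidationError(
                f"grouping column {self.grouping_column!r} contains empty labels"
            )
        if self.control_label is not None and self.control_label not in set(labels):
            raise ValidationError(
                f"control label {self.control_label!r} does not occur in "
                f"grouping column {self.grouping_column!r} "
                f"(labels: {sorted(set(labels))})"
            )

    @property
    def samples(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def groups(self) -> list[str]:
        """Distinct grouping labels in first-occurrence order."""
        seen: dict[str, None] = {}
        for lab in self.table[self.grouping_column].astype(str):
            seen.setdefault(lab, None)
        return list(seen)

    def group_samples(self) -> dict[str, list[str]]:
        labels = self.table[self.grouping_column].astype(str)
        return {g: labels.index[labels == g].tolist() for g in self.groups}


@dataclass
class GeneSetCollection:
    """Named gene sets (Hallmark/GO/KEGG/Reactome-style or TF-target libraries).

    ``sets`` maps set name to an ordered tuple of unique gene identifiers;
    membership order is preserved from the source for round-trip fidelity.
    """

    sets: dict[str, tuple[str, ...]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} contains duplicate genes")

    def as_set(self, name: str) -> frozenset[str]:
        return frozenset(self.sets[name])

    def __len__(self) -> int:
        return len(self.sets)


RESULT_SLOTS = (
    "variance_curves",
    "correlations",
    "cutoff_statistics",
    "gfc",
    "layer_networks",
    "integrated_network",
    "partition",
    "module_summary",
    "enrichments",
)


@dataclass
class AnalysisState:
    """Unified container for layers, parameters, and per-stage results.

    Result slots are fixed (see :data:`RESULT_SLOTS`); a slot is either
    ``None`` (stage not run) or holds that stage's complete output.
    Parameters consumed by a stage are recorded in ``parameters`` before the
    stage runs, so the state fully documents the analysis.
    """

    layers: list[tuple[ExpressionLayer, AnnotationTable]]
    parameters: dict = field(default_factory=dict)
    results: dict = field(default_factory=lambda: {s: None for s in RESULT_SLOTS})

    def layer(self, name: str) -> tuple[ExpressionLayer, AnnotationTable]:
        for lay, ann in self.layers:
            if lay.name == name:
                return lay, ann
        raise KeyError(f"no layer named {name!r}")

    @property
    def layer_names(self) -> list[str]:
        return [lay.name for lay, _ in self.layers]

    def set_result(self, slot: str, value) -> None:
        if slot not in self.results:
            raise KeyError(f"unknown result slot {slot!r}; valid: {RESULT_SLOTS}")
        self.results[slot] = value


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ValidationError(
        f"{path}: could not detect delimiter (expected tab or comma in header)"
    )


def _read_table(path, delimiter: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _detect_delimiter(path)
    return pd.read_csv(path, sep=sep, index_col=0, dtype=object)


def read_expression(path, delimiter: Optional[str] = None, name: Optional[str] = None) -> ExpressionLayer:
    """Read a gene-by-sample expression matrix from delimited text.

    Raises
    ------
    ValidationError
        On duplicate gene rows (listing the duplicates) or missing /
        non-numeric cells (naming row and column).
    """
    path = Path(path)
    df = _read_table(path, delimiter)
    df.index = df.index.astype(str).str.strip()
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate gene rows: {dup}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.index[coerced.isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: missing or non-numeric value at gene {bad[0]!r}, "
                f"sample {col!r}"
            )
        numeric[col] = coerced.to_numpy(dtype=float)
    numeric.index.name = None
    if numeric.shape[0] < 2:
        raise ValidationError(f"{path}: need at least 2 gene rows")
    return ExpressionLayer(name=name or path.stem, values=numeric)


def write_expression(layer: ExpressionLayer, path, delimiter: str = "\t") -> None:
    """Write a layer's matrix; float formatting round-trips at full precision."""
    out = layer.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=delimiter)


def read_annotation(
    path,
    grouping_column: str,
    control_label: Optional[str] = None,
    delimiter: Optional[str] = None,
) -> AnnotationTable:
    """Read a samples-by-categories annotation table."""
    df = _read_table(path, delimiter)
    df.index.name = None
    return AnnotationTable(
        table=df, grouping_column=grouping_column, control_label=control_label
    )


def write_annotation(annotation: AnnotationTable, path, delimiter: str = "\t") -> None:
    out = annotation.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep=delimiter)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Within-set duplicate genes are collapsed (first occurrence kept); lines
    with fewer than three fields and duplicate set names are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, tuple[str, ...]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise ValidationError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = tuple(genes)
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def validate_state(
    layers: list[ExpressionLayer], annotations: list[AnnotationTable]
) -> AnalysisState:
    """Pair layers with annotations positionally and cross-validate samples.

    Every annotation's sample set must exactly match its layer's sample set;
    mismatches raise a :class:`ValidationError` naming the layer and the
    offending samples.
    """
    if len(layers) == 0:
        raise ValidationError("at least one layer is required")
    if len(layers) != len(annotations):
        raise ValidationError(
            f"{len(layers)} layers but {len(annotations)} annotations; "
            "pairing is positional and counts must match"
        )
    names = [lay.name for lay in layers]
    if len(set(names)) != len(names):
        raise ValidationError(f"layer names not unique: {names}")
    pairs = []
    for lay, ann in zip(layers, annotations):
        lay_s, ann_s = set(lay.samples), set(ann.samples)
        if lay_s != ann_s:
            missing = sorted(lay_s - ann_s)
            extra = sorted(ann_s - lay_s)
            raise ValidationError(
                f"layer {lay.name!r}: annotation sample mismatch "
                f"(missing from annotation: {missing}; not in layer: {extra})"
            )
        pairs.append((lay, ann))
    return AnalysisState(layers=pairs)
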