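"""Group Fold-Change (GFC) computation.

The GFC summarizes a gene's expression trend over condition groups within
one layer. With ``X`` the set of group labels and ``mean_g(x_i)`` the mean
expression of gene ``g`` in group ``x_i``:

* **no-control mode** — GFC(g, x_i) = mean_g(x_i) / ((1/|X|) Σ_j mean_g(x_j)),
  i.e. each group mean relative to the unweighted average of the gene's
  group means. The GFCs of a gene therefore average exactly 1 across groups.
* **with-control mode** — GFC(g, x_i) = mean_g(x_i) / mean_g(x_c), the
  ratio to the control group's mean, computed within each layer
  independently so that layers with unmatched designs remain comparable.

GFCs are raw ratios; an optional log2 transform is available but off by
default. A zero (or negative-to-zero) denominator makes the gene's GFCs
undefined: the gene's row becomes NaN with a warning, never a clamped value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import AnnotationTable, ExpressionLayer, ValidationError

__all__ = [
    "GroupMeansTable",
    "GfcTable",
    "group_means",
    "gfc_no_control",
    "gfc_with_control",
    "compute_gfc",
    "write_gfc",
]


@dataclass
class GroupMeansTable:
    """Per-gene mean expression in each condition group of one layer."""

    layer_name: str
    means: pd.DataFrame  # genes x groups
    control: Optional[str] = None

    def __post_init__(self) -> None:
        if self.control is not None and self.control not in self.means.columns:
            raise ValidationError(
                f"control group {self.control!r} not among groups "
                f"{list(self.means.columns)}"
            )

    @property
    def groups(self) -> list[str]:
        return self.means.columns.tolist()

    @property
    def genes(self) -> list[str]:
        return self.means.index.tolist()


@dataclass
class GfcTable:
    """Gene-by-group GFC values for one layer.

    ``mode`` is ``no_control`` or ``with_control``; in with-control mode the
    control column is identically 1 (where defined). Undefined GFCs are NaN.
    """

    layer_name: str
    mode: str
    values: pd.DataFrame  # genes x groups
    control: Optional[str] = None
    log2: bool = False

    @property
    def groups(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()


def group_means(layer: ExpressionLayer, annotation: AnnotationTable) -> GroupMeansTable:
    """Arithmetic mean expression per gene per condition group.

    Groups are the distinct labels of the annotation's grouping column (no
    merging); every sample belongs to exactly one group.
    """
    if set(annotation.samples) != set(layer.samples):
        raise ValidationError(
            f"layer {layer.name!r}: annotation samples do not match layer samples"
        )
    cols = {}
    for label, samples in annotation.group_samples().items():
        if len(samples) == 0:
            raise ValidationError(f"group {label!r} has no samples")
        cols[label] = layer.values[samples].mean(axis=1)
    means = pd.DataFrame(cols)
    return GroupMeansTable(
        layer_name=layer.name, means=means, control=annotation.control_label
    )


def _finish(values: pd.DataFrame, log2: bool) -> pd.DataFrame:
    if log2:
        with np.errstate(divide="ignore", invalid="ignore"):
            arr = np.log2(values.to_numpy())
        arr[~np.isfinite(arr)] = np.nan
        return pd.DataFrame(arr, index=values.index, columns=values.columns)
    return values


def gfc_no_control(means: GroupMeansTable, log2: bool = False) -> GfcTable:
    """GFCs relative to the unweighted average of the gene's group means.

    Genes whose grand mean of group means is zero get an all-NaN row and a
    warning; by construction every defined row averages exactly 1 (before
    the optional log2 transform).
    """
    if means.control is not None:
        raise ValidationError(
            "no-control GFC requested but a control label is set; "
            "use gfc_with_control or drop the control label"
        )
    M = means.means
    grand = M.mean(axis=1)  # unweighted mean over groups
    undefined = grand == 0
    if undefined.any():
        warnings.warn(
            f"layer {means.layer_name!r}: {int(undefined.sum())} gene(s) with "
            "zero grand mean; their GFCs are undefined (NaN)",
            stacklevel=2,
        )
    denom = grand.where(~undefined)
    values = M.div(denom, axis=0)
    return GfcTable(
        layer_name=means.layer_name,
        mode="no_control",
        values=_finish(values, log2),
        log2=log2,
    )


def gfc_with_control(means: GroupMeansTable, log2: bool = False) -> GfcTable:
    """GFCs as ratios to the control group's mean, layer-locally.

    The control column is identically 1 for defined genes. Genes with a
    zero control mean are flagged and their whole row set to NaN.
    """
    if means.control is None:
        raise ValidationError("with-control GFC requires a control label")
    M = means.means
    ctrl = M[means.control]
    undefined = ctrl == 0
    if undefined.any():
        warnings.warn(
            f"layer {means.layer_name!r}: {int(undefined.sum())} gene(s) with "
            "zero control mean; their GFCs are undefined (NaN)",
            stacklevel=2,
        )
    denom = ctrl.where(~undefined)
    values = M.div(denom, axis=0)
    return GfcTable(
        layer_name=means.layer_name,
        mode="with_control",
        values=_finish(values, log2),
        control=means.control,
        log2=log2,
    )


def compute_gfc(
    layer: ExpressionLayer, annotation: AnnotationTable, log2: bool = False
) -> GfcTable:
    """Group means + the GFC mode implied by the annotation's control label."""
    means = group_means(layer, annotation)
    if annotation.control_label is None:
        return gfc_no_control(means, log2=log2)
    return gfc_with_control(means, log2=log2)


def write_gfc(tables: list[GfcTable], path) -> None:
    """Write GFC tables as long TSV: gene, layer, group, gfc."""
    rows = []
    for tab in tables:
        long = tab.values.stack(future_stack=True).reset_index()
        long.columns = ["gene", "group", "gfc"]
        long.insert(1, "layer", tab.layer_name)
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
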