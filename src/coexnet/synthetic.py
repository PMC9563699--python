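"""Synthetic multi-layer expression data with planted co-expression modules.

The generator emulates the inputs the pipeline consumes — several layers of
*normalized* gene-by-sample expression with shared gene identifiers — using
a latent-factor Gaussian model: every planted module m has, per layer and
sample, a latent factor f_{m,s} ~ N(0,1), and each of its genes reads

    value(g, s) = effect[m, group(s)] * base + sd * (sqrt(rho) * f_{m,s}
                                                     + sqrt(1-rho) * e_{g,s})

with e_{g,s} ~ N(0,1) i.i.d., so any two genes of the module correlate at
rho (``within_module_corr``) within a group, while the group-dependent
multiplier plants condition effects whose with-control GFC equals the
effect ratio. Background genes are pure noise around ``base``. The positive
``base`` keeps all values (and hence GFC denominators) positive at the
default noise scale. All randomness flows from one seed through a single
generator, recorded in the returned :class:`SyntheticTruth`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationTable, ExpressionLayer, ValidationError, write_annotation, write_expression

__all__ = ["SyntheticTruth", "generate_layers", "standard_fixture", "write_fixture"]

# default planted effect multipliers, cycled over modules; each module gets
# one affected non-control group, the first module the strong 2.0 effect
_DEFAULT_EFFECTS = (2.0, 0.5, 1.5, 0.75, 1.25)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated fixture: planted memberships, effects,
    noise scales and the seed that reproduces the matrices exactly."""

    module_genes: dict[str, list[str]]
    background_genes: list[str]
    effects: dict[str, dict[str, float]]  # module -> group -> multiplier
    within_module_corr: float
    noise_sd: float
    base_level: float
    control_label: Optional[str]
    seed: int

    def labels(self) -> dict[str, str]:
        """Gene -> planted module label (background genes excluded)."""
        return {g: m for m, gs in self.module_genes.items() for g in gs}


def _default_effect_map(
    n_modules: int, groups: Sequence[str], control_label: Optional[str]
) -> dict[str, dict[str, float]]:
    non_control = [g for g in groups if g != control_label]
    effects: dict[str, dict[str, float]] = {}
    for m in range(n_modules):
        label = f"M{m + 1}"
        effects[label] = {g: 1.0 for g in groups}
        if non_control:
            target = non_control[m % len(non_control)]
            effects[label][target] = _DEFAULT_EFFECTS[m % len(_DEFAULT_EFFECTS)]
    return effects


def generate_layers(
    n_layers: int = 2,
    n_modules: int = 5,
    genes_per_module: int = 40,
    n_background: int = 200,
    groups: Sequence[str] = ("ctrl", "A", "B"),
    samples_per_group: int = 10,
    within_module_corr: float = 0.95,
    effect_map: Optional[dict[str, dict[str, float]]] = None,
    noise_sd: float = 1.0,
    base_level: float = 10.0,
    control_label: Optional[str] = "ctrl",
    seed: int = 1,
) -> tuple[list[ExpressionLayer], list[AnnotationTable], SyntheticTruth]:
    """Generate ``n_layers`` expression layers with planted modules.

    Defaults are the standard benchmark conditions: 2 layers, 5 modules of
    40 genes plus 200 background genes, 3 groups (ctrl/A/B) of 10 samples,
    within-module correlation 0.95, unit noise around a base level of 10.
    The default effect map gives each module one affected non-control group;
    module M1 carries the strong 2.0 effect in group A.
    """
    if not 0 < within_module_corr < 1:
        raise ValidationError("within_module_corr must lie in (0, 1)")
    if min(n_layers, n_modules, genes_per_module, samples_per_group) < 1 or n_background < 0:
        raise ValidationError("all counts must be >= 1 (background >= 0)")
    groups = list(groups)
    if not groups:
        raise ValidationError("need at least one group label")
    if control_label is not None and control_label not in groups:
        raise ValidationError(f"control label {control_label!r} not in groups {groups}")

    if effect_map is None:
        effect_map = _default_effect_map(n_modules, groups, control_label)
    module_labels = list(effect_map)
    if len(module_labels) != n_modules:
        raise ValidationError("effect_map must have one entry per module")

    rng = np.random.default_rng(seed)
    module_genes = {
        m: [f"{m}_G{i:03d}" for i in range(genes_per_module)] for m in module_labels
    }
    background = [f"BG_G{i:03d}" for i in range(n_background)]
    genes = [g for gs in module_genes.values() for g in gs] + background

    group_of = np.repeat(groups, samples_per_group)
    rho, sd = within_module_corr, noise_sd
    layers, annotations = [], []
    for layer_idx in range(n_layers):
        lname = f"layer{layer_idx + 1}"
        samples = [
            f"{lname}_{grp}_{s + 1:02d}"
            for grp in groups
            for s in range(samples_per_group)
        ]
        n_samples = len(samples)
        values = np.empty((len(genes), n_samples))
        row = 0
        for m in module_labels:
            factor = rng.standard_normal(n_samples)
            eps = rng.standard_normal((genes_per_module, n_samples))
            signal = np.sqrt(rho) * factor[None, :] + np.sqrt(1 - rho) * eps
            eff = np.array([effect_map[m][g] for g in group_of])
            values[row : row + genes_per_module] = eff[None, :] * base_level + sd * signal
            row += genes_per_module
        if n_background:
            values[row:] = base_level + sd * rng.standard_normal((n_background, n_samples))
        if values.min() <= 0:
            shift = -values.min() + 1e-3
            warnings.warn(
                f"{lname}: shifting all values by {shift:.4g} to keep them "
                "positive; planted GFC ratios are perturbed",
                stacklevel=2,
            )
            values = values + shift
        layers.append(
            ExpressionLayer(
                name=lname,
                values=pd.DataFrame(values, index=genes, columns=samples),
            )
        )
        annotations.append(
            AnnotationTable(
                table=pd.DataFrame({"condition": group_of}, index=samples),
                grouping_column="condition",
                control_label=control_label,
            )
        )

    truth = SyntheticTruth(
        module_genes=module_genes,
        background_genes=background,
        effects=effect_map,
        within_module_corr=within_module_corr,
        noise_sd=noise_sd,
        base_level=base_level,
        control_label=control_label,
        seed=seed,
    )
    return layers, annotations, truth


def standard_fixture(seed: int = 1):
    """The standard benchmark fixture at default generator conditions."""
    return generate_layers(seed=seed)


def write_fixture(
    layers: Sequence[ExpressionLayer],
    annotations: Sequence[AnnotationTable],
    directory,
) -> dict[str, Path]:
    """Write a generated fixture in the exact TSV formats the readers accept."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for lay, ann in zip(layers, annotations):
        expr = directory / f"{lay.name}_expression.tsv"
        anno = directory / f"{lay.name}_annotation.tsv"
        write_expression(lay, expr)
        write_annotation(ann, anno)
        paths[f"{lay.name}_expression"] = expr
        paths[f"{lay.name}_annotation"] = anno
    return paths
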