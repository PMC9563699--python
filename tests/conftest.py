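import numpy as np
import pandas as pd
import pytest

import coexnet as cx


@pytest.fixture
def small_layer() -> cx.ExpressionLayer:
    """3 genes x 4 samples with easily hand-checked values."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0],
            "s2": [2.0, 2.0, 6.0],
            "s3": [3.0, 4.0, 5.0],
            "s4": [4.0, 4.0, 6.0],
        },
        index=["gA", "gB", "gC"],
    )
    return cx.ExpressionLayer(name="demo", values=values)


@pytest.fixture
def small_annotation() -> cx.AnnotationTable:
    table = pd.DataFrame(
        {"condition": ["ctrl", "ctrl", "stim", "stim"]},
        index=["s1", "s2", "s3", "s4"],
    )
    return cx.AnnotationTable(table=table, grouping_column="condition", control_label="ctrl")


@pytest.fixture(scope="session")
def standard_fixture():
    """The default synthetic benchmark: 2 layers, 5 planted modules x 40
    genes, 200 background genes, 3 groups x 10 samples, corr 0.95, seed 1."""
    return cx.standard_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, standard_fixture):
    layers, annotations, _ = standard_fixture
    d = tmp_path_factory.mktemp("fixture")
    cx.write_fixture(layers, annotations, d)
    return d


def make_run_config(fixture_dir, output_dir, **overrides) -> cx.RunConfig:
    layer_names = sorted(p.name.replace("_expression.tsv", "")
                         for p in fixture_dir.glob("*_expression.tsv"))
    layers = [
        cx.LayerConfig(
            name=n,
            expression=str(fixture_dir / f"{n}_expression.tsv"),
            annotation=str(fixture_dir / f"{n}_annotation.tsv"),
            grouping_column="condition",
            control_label="ctrl",
        )
        for n in layer_names
    ]
    return cx.RunConfig(layers=layers, output_dir=str(output_dir), **overrides)


@pytest.fixture(scope="session")
def pipeline_output(fixture_dir, tmp_path_factory):
    """One full default-parameter pipeline run on the standard fixture."""
    out = tmp_path_factory.mktemp("pipeline")
    config = make_run_config(fixture_dir, out / "run")
    return cx.run_pipeline(config)


def random_correlation_result(rng, n_genes=12, layer_name="L"):
    """A valid symmetric correlation matrix from random data."""
    X = rng.standard_normal((n_genes, 8))
    layer = cx.ExpressionLayer(
        name=layer_name,
        values=pd.DataFrame(
            X,
            index=[f"g{i:02d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(8)],
        ),
    )
    return cx.compute_correlations(layer, "pearson")
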