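"""Variance ranking, inflection suggestion, correlations, cut-off statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

import coexnet as cx
from coexnet.io import ValidationError

from oracle_util import least_squares_r2


def layer_from_rows(rows: dict[str, list[float]]) -> cx.ExpressionLayer:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return cx.ExpressionLayer(name="L", values=df)


class TestRankVariances:
    def test_descending_variance_order(self):
        layer = layer_from_rows(
            {"g1": [0, 2, 4], "g2": [0, 1, 2], "g3": [0, 3, 6]}  # vars 4, 1, 9
        )
        curve = cx.rank_variances(layer)
        assert curve.genes == ["g3", "g1", "g2"]
        np.testing.assert_allclose(curve.variances, [9, 4, 1])

    def test_tie_broken_by_gene_id(self):
        layer = layer_from_rows({"gB": [1, 2, 3], "gA": [4, 5, 6], "gC": [0, 0, 1]})
        curve = cx.rank_variances(layer)
        assert curve.genes[:2] == ["gA", "gB"]  # identical variance 1

    def test_zero_variance_genes_last_and_flagged(self):
        layer = layer_from_rows({"g1": [1, 2, 3], "g2": [5, 5, 5]})
        curve = cx.rank_variances(layer)
        assert curve.genes[-1] == "g2"
        assert curve.zero_variance_genes == ["g2"]
        assert len(curve.log_variance) == 1  # positive-variance prefix only

    def test_all_constant_errors(self):
        layer = layer_from_rows({"g1": [2, 2, 2], "g2": [7, 7, 7]})
        with pytest.raises(ValidationError, match="constant"):
            cx.rank_variances(layer)


class TestSuggestTopvar:
    @staticmethod
    def _curve(variances: np.ndarray) -> cx.VarianceCurve:
        order = np.argsort(-variances, kind="mergesort")
        return cx.VarianceCurve(
            genes=[f"g{i:04d}" for i in order],
            variances=variances[order],
            zero_variance_genes=[],
        )

    def test_planted_elbow_detected_near_truth(self):
        rng = np.random.default_rng(11)
        variances = np.concatenate(
            [10.0 * np.exp(rng.normal(0, 0.05, 100)), 0.1 * np.exp(rng.normal(0, 0.05, 900))]
        )
        curve = self._curve(variances)
        suggestion = cx.suggest_topvar(curve)
        assert 90 <= suggestion <= 110
        # independent scan: the max |second difference| of the smoothed
        # log-variance curve must sit at the same rank
        y = curve.log_variance
        w = 11  # max(5, 1% of 1000), odd
        ys = np.array([y[i - 5 : i + 6].mean() for i in range(5, len(y) - 5)])
        d2 = np.abs(ys[2:] - 2 * ys[1:-1] + ys[:-2])
        assert suggestion == int(np.argmax(d2)) + 7  # first d2 rank = w//2 + 2

    def test_exactly_linear_curve_falls_back_with_warning(self):
        variances = 10.0 ** (-0.01 * np.arange(300))
        curve = self._curve(variances)
        with pytest.warns(UserWarning, match="no inflection"):
            assert cx.suggest_topvar(curve) == 300

    def test_short_curve_falls_back_with_warning(self):
        curve = self._curve(np.array([4.0, 2.0, 1.0]))
        with pytest.warns(UserWarning, match="window"):
            assert cx.suggest_topvar(curve) == 3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_suggestion_in_range_for_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        variances = np.exp(rng.normal(0, 2, rng.integers(10, 400)))
        curve = self._curve(variances)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert 1 <= cx.suggest_topvar(curve) <= len(curve)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        variances = np.exp(rng.normal(0, 2, 200))
        a = cx.suggest_topvar(self._curve(variances))
        b = cx.suggest_topvar(self._curve(variances * 37.5))
        assert a == b


class TestFilterTopVariant:
    def test_full_count_is_identity(self, small_layer):
        out = cx.filter_top_variant(small_layer, small_layer.n_genes)
        pd.testing.assert_frame_equal(out.values, small_layer.values)

    def test_n_one_keeps_maximal_variance_gene(self):
        layer = layer_from_rows({"g1": [0, 2, 4], "g2": [0, 1, 2], "g3": [0, 3, 6]})
        assert cx.filter_top_variant(layer, 1).genes == ["g3"]

    def test_boundary_tie_keeps_lower_gene_id(self):
        layer = layer_from_rows(
            {"gB": [1, 2, 3], "gA": [4, 5, 6], "gC": [0, 0, 0.1]}
        )
        assert cx.filter_top_variant(layer, 1).genes == ["gA"]

    def test_out_of_range_errors(self, small_layer):
        with pytest.raises(ValidationError, match="out of range"):
            cx.filter_top_variant(small_layer, 99)


class TestCorrelations:
    def test_identical_profiles_give_one_under_both_methods(self):
        layer = layer_from_rows({"g1": [1, 2, 3, 4], "g2": [2, 4, 6, 8], "g3": [5, 1, 2, 9]})
        for method in ("pearson", "spearman"):
            corr = cx.compute_correlations(layer, method)
            assert corr.pair("g1", "g2") == pytest.approx(1.0)

    def test_monotone_nonlinear_profiles(self):
        layer = layer_from_rows({"g1": [1, 2, 3], "g2": [1, 4, 9], "g3": [3, 1, 2]})
        sp = cx.compute_correlations(layer, "spearman")
        pe = cx.compute_correlations(layer, "pearson")
        assert sp.pair("g1", "g2") == pytest.approx(1.0)
        assert pe.pair("g1", "g2") < 1.0
        expected, _ = sstats.pearsonr([1, 2, 3], [1, 4, 9])
        assert pe.pair("g1", "g2") == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_is_undefined_not_pm_one(self):
        layer = layer_from_rows({"g1": [1, 2, 3], "g2": [4, 4, 4]})
        for method in ("pearson", "spearman"):
            corr = cx.compute_correlations(layer, method)
            assert np.isnan(corr.pair("g1", "g2"))
            assert corr.constant_genes == ["g2"]

    def test_too_few_samples_errors(self):
        values = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(Exception):
            layer = cx.ExpressionLayer(name="L", values=values)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_agrees_with_scipy_on_random_matrix(self, method):
        rng = np.random.default_rng(17)
        layer = layer_from_rows(
            {f"g{i:02d}": rng.standard_normal(10).tolist() for i in range(50)}
        )
        corr = cx.compute_correlations(layer, method)
        fn = sstats.pearsonr if method == "pearson" else sstats.spearmanr
        for i in range(0, 50, 7):
            for j in range(i + 1, 50, 11):
                ref = fn(
                    layer.values.iloc[i].to_numpy(), layer.values.iloc[j].to_numpy()
                )[0]
                assert corr.matrix[i, j] == pytest.approx(ref, abs=1e-12)

    def test_precomputed_matrix_accepted(self):
        M = np.array([[1.0, 0.5], [0.5, 1.0]])
        corr = cx.correlation_from_matrix(["a", "b"], M)
        assert corr.pair("a", "b") == 0.5
        assert corr.method == "precomputed"


class TestCutoffStatistics:
    def test_cutoff_above_max_coefficient_gives_empty_counts(self):
        corr = cx.correlation_from_matrix(
            ["a", "b", "c"],
            np.array([[1, 0.5, 0.4], [0.5, 1, 0.3], [0.4, 0.3, 1.0]]),
        )
        st_ = cx.cutoff_statistics(corr, [0.9])
        assert st_.n_edges[0] == 0 and st_.n_nodes[0] == 0 and st_.n_components[0] == 0

    def test_complete_graph_counts(self):
        G = 5
        M = np.full((G, G), 0.95)
        np.fill_diagonal(M, 1.0)
        corr = cx.correlation_from_matrix([f"g{i}" for i in range(G)], M)
        st_ = cx.cutoff_statistics(corr, [0.9])
        assert st_.n_edges[0] == G * (G - 1) // 2
        assert st_.n_nodes[0] == G and st_.n_components[0] == 1

    def test_counts_monotone_non_increasing_on_random_input(self):
        rng = np.random.default_rng(23)
        from conftest import random_correlation_result

        corr = random_correlation_result(rng, n_genes=20)
        grid = np.linspace(0.05, 0.95, 30)
        st_ = cx.cutoff_statistics(corr, grid)
        assert np.all(np.diff(st_.n_edges) <= 0)
        assert np.all(np.diff(st_.n_nodes) <= 0)

    def test_empty_cutoff_list_errors(self):
        corr = cx.correlation_from_matrix(["a", "b"], np.array([[1, 0.5], [0.5, 1]]))
        with pytest.raises(ValidationError, match="empty"):
            cx.cutoff_statistics(corr, [])


class TestDegreeDistributionR2:
    def test_star_graph_two_distinct_degrees_fit_exactly(self):
        assert cx.degree_distribution_r2([5, 1, 1, 1, 1, 1]) == pytest.approx(1.0)

    def test_single_distinct_degree_undefined(self):
        assert np.isnan(cx.degree_distribution_r2([2, 2, 2, 2]))

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError):
            cx.degree_distribution_r2([])

    def test_matches_bruteforce_least_squares_on_random_graphs(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            degrees = rng.integers(0, 15, size=rng.integers(5, 60))
            pos = degrees[degrees > 0]
            if pos.size == 0 or np.unique(pos).size < 2:
                continue
            distinct, counts = np.unique(pos, return_counts=True)
            expected = least_squares_r2(np.log10(distinct), np.log10(counts))
            assert cx.degree_distribution_r2(degrees) == pytest.approx(expected, abs=1e-12)


class TestSuggestCutoff:
    def test_picks_max_r2_among_node_preserving_cutoffs(self, standard_fixture):
        layers, _, _ = standard_fixture
        corr = cx.compute_correlations(layers[0], "spearman")
        st_ = cx.cutoff_statistics(corr)
        chosen = cx.suggest_cutoff(st_)
        idx = list(st_.cutoffs).index(chosen)
        candidates = st_.n_nodes >= 0.9 * st_.n_nodes.max()
        assert candidates[idx]
        assert st_.r_squared[idx] == np.nanmax(st_.r_squared[candidates])
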