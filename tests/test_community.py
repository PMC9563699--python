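"""Module detection, size filter, GFC summaries, condition ordering, hubs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import coexnet as cx
from coexnet.io import ValidationError

from oracle_util import complete_linkage_merge_heights


def wrap(G: nx.Graph, default_weight=1.0) -> cx.CoexpressionNetwork:
    H = nx.Graph()
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", default_weight))
        H.add_edge(str(u), str(v), weight=w, layer_weights={"L": w})
    return cx.CoexpressionNetwork(graph=H, origin="single_layer", name="L", layer_names=["L"])


def two_cliques(size=30) -> cx.CoexpressionNetwork:
    G = nx.Graph()
    for offset, prefix in ((0, "a"), (size, "b")):
        for i, j in itertools.combinations(range(size), 2):
            G.add_edge(f"{prefix}{i:02d}", f"{prefix}{j:02d}", weight=0.95)
    return wrap(G)


class TestDetectModules:
    @pytest.mark.parametrize("algorithm", ["leiden", "louvain", "fast_greedy"])
    def test_two_disconnected_cliques_split_exactly(self, algorithm):
        net = two_cliques()
        part = cx.detect_modules(net, algorithm=algorithm)
        modules = part.modules()
        assert len(modules) == 2
        memberships = {frozenset(genes) for genes in modules.values()}
        assert memberships == {
            frozenset(f"a{i:02d}" for i in range(30)),
            frozenset(f"b{i:02d}" for i in range(30)),
        }

    def test_planted_partition_recovered(self):
        G = nx.planted_partition_graph(4, 50, 0.6, 0.02, seed=42)
        truth = [i // 50 for i in range(200)]
        part = cx.detect_modules(wrap(G), algorithm="leiden", seed=1)
        detected = [part.assignment[str(i)] for i in range(200)]
        assert adjusted_rand_score(truth, detected) >= 0.9

    def test_same_seed_reproduces_assignment(self):
        G = nx.planted_partition_graph(3, 40, 0.5, 0.05, seed=7)
        net = wrap(G)
        a = cx.detect_modules(net, seed=5)
        b = cx.detect_modules(net, seed=5)
        assert a.assignment == b.assignment

    def test_unknown_algorithm_lists_options(self):
        with pytest.raises(ValidationError, match="leiden"):
            cx.detect_modules(two_cliques(), algorithm="kmeans")

    def test_labels_are_colors_by_descending_size(self):
        G = nx.Graph()
        for i, j in itertools.combinations(range(10), 2):
            G.add_edge(f"a{i}", f"a{j}", weight=0.9)
        for i, j in itertools.combinations(range(5), 2):
            G.add_edge(f"b{i}", f"b{j}", weight=0.9)
        part = cx.detect_modules(wrap(G))
        assert part.labels == ["turquoise", "blue"]
        assert part.sizes()["turquoise"] == 10

    def test_consistent_gene_renaming_permutes_membership_not_labels(self):
        net = two_cliques()
        part = cx.detect_modules(net)
        renamed = nx.relabel_nodes(net.graph, lambda g: "x" + g)
        part2 = cx.detect_modules(
            cx.CoexpressionNetwork(graph=renamed, origin="single_layer", name="L")
        )
        assert part.labels == part2.labels
        for label in part.labels:
            assert {"x" + g for g in part.genes(label)} == set(part2.genes(label))


class TestFilterMinSize:
    def _partition(self, sizes: dict[str, int]) -> cx.ModulePartition:
        assignment = {}
        for label, n in sizes.items():
            for i in range(n):
                assignment[f"{label}{i:03d}"] = label
        return cx.ModulePartition(assignment=assignment)

    def test_small_module_dissolved_to_unassigned(self):
        part = self._partition({"big": 30, "small": 24})
        out = cx.filter_min_size(part, min_size=25)
        assert set(out.assignment.values()) == {"turquoise"}
        assert len(out.unassigned) == 24
        assert out.min_size == 25

    def test_min_size_one_is_identity(self):
        part = self._partition({"x": 3, "y": 2})
        out = cx.filter_min_size(part, min_size=1)
        assert len(out.assignment) == 5 and not out.unassigned

    def test_everything_below_threshold_empties_partition(self):
        part = self._partition({"x": 3, "y": 2})
        out = cx.filter_min_size(part, min_size=10)
        assert out.assignment == {} and len(out.unassigned) == 5
        assert out.labels == []

    def test_invalid_min_size_errors(self):
        with pytest.raises(ValidationError):
            cx.filter_min_size(self._partition({"x": 3}), min_size=0)


def gfc_table(layer: str, values: dict, index: list) -> cx.GfcTable:
    return cx.GfcTable(
        layer_name=layer, mode="with_control", values=pd.DataFrame(values, index=index)
    )


class TestModuleSummary:
    def test_single_gene_module_row_equals_gene_vector(self):
        part = cx.ModulePartition(assignment={"g1": "solo", "g2": "solo2"})
        tab = gfc_table("L1", {"ctrl": [1.0, 1.0], "stim": [2.5, 0.5]}, ["g1", "g2"])
        summary = cx.module_summary(part, [tab])
        assert summary.table.loc["solo", ("L1", "stim")] == pytest.approx(2.5)

    def test_uniform_module_gfc_passes_through(self):
        part = cx.ModulePartition(assignment={f"g{i}": "m" for i in range(4)})
        tab = gfc_table("L1", {"stim": [1.5] * 4}, [f"g{i}" for i in range(4)])
        summary = cx.module_summary(part, [tab])
        assert summary.table.loc["m", ("L1", "stim")] == pytest.approx(1.5)

    def test_genes_absent_from_a_layer_excluded_from_its_cells(self):
        part = cx.ModulePartition(assignment={f"g{i}": "m" for i in range(4)})
        t1 = gfc_table("L1", {"stim": [1.0, 2.0, 3.0, 4.0]}, [f"g{i}" for i in range(4)])
        t2 = gfc_table("L2", {"stim": [10.0, 20.0]}, ["g0", "g1"])  # g2, g3 unmeasured
        summary = cx.module_summary(part, [t1, t2])
        assert summary.table.loc["m", ("L1", "stim")] == pytest.approx(2.5)
        assert summary.table.loc["m", ("L2", "stim")] == pytest.approx(15.0)  # mean of present only

    def test_all_undefined_cell_is_nan(self):
        part = cx.ModulePartition(assignment={"g0": "m", "g1": "m"})
        tab = gfc_table("L1", {"stim": [np.nan, np.nan]}, ["g0", "g1"])
        summary = cx.module_summary(part, [tab])
        assert np.isnan(summary.table.loc["m", ("L1", "stim")])

    def test_sizes_sum_to_assigned_count(self, standard_fixture):
        layers, annotations, _ = standard_fixture
        part = cx.ModulePartition(
            assignment={g: "m1" if i % 2 else "m2" for i, g in enumerate(layers[0].genes)}
        )
        gfcs = [cx.compute_gfc(l, a) for l, a in zip(layers, annotations)]
        summary = cx.module_summary(part, gfcs)
        assert sum(summary.sizes.values()) == len(part.assignment)


class TestOrderConditions:
    def _summary(self, matrix: np.ndarray, cols: list) -> cx.ModuleSummary:
        table = pd.DataFrame(
            matrix,
            index=[f"m{i}" for i in range(matrix.shape[0])],
            columns=pd.MultiIndex.from_tuples(cols),
        )
        return cx.ModuleSummary(table=table, sizes={m: 1 for m in table.index})

    def test_duplicated_columns_become_adjacent_leaves(self):
        M = np.array([[1.0, 5.0, 1.0], [2.0, 9.0, 2.0], [0.5, 3.0, 0.5]])
        cols = [("L", "a"), ("L", "b"), ("L", "c")]  # a == c
        out = cx.order_conditions(self._summary(M, cols))
        order = out.column_order
        ia, ic = order.index(("L", "a")), order.index(("L", "c"))
        assert abs(ia - ic) == 1
        assert out.linkage[0, 2] == pytest.approx(0.0)  # first merge at height 0

    def test_two_columns_single_merge(self):
        M = np.array([[1.0, 2.0], [3.0, 1.0]])
        out = cx.order_conditions(self._summary(M, [("L", "a"), ("L", "b")]))
        assert out.column_order == [("L", "a"), ("L", "b")]
        assert out.linkage.shape == (1, 4)

    def test_merge_heights_match_bruteforce_complete_linkage(self):
        rng = np.random.default_rng(53)
        M = rng.normal(size=(6, 4))
        out = cx.order_conditions(
            self._summary(M, [("L", c) for c in "abcd"]), method="complete"
        )
        expected = complete_linkage_merge_heights(M)
        np.testing.assert_allclose(sorted(out.linkage[:, 2]), sorted(expected), atol=1e-12)

    def test_undefined_cells_use_pairwise_complete_with_warning(self):
        M = np.array([[1.0, 2.0, np.nan], [3.0, 1.0, 2.0], [0.0, 1.0, 1.5]])
        with pytest.warns(UserWarning, match="pairwise-complete"):
            out = cx.order_conditions(self._summary(M, [("L", c) for c in "abc"]))
        assert len(out.column_order) == 3


class TestHubGenes:
    def test_star_center_ranks_first(self):
        G = nx.star_graph(8)
        net = wrap(G)
        part = cx.ModulePartition(assignment={str(i): "m" for i in range(9)})
        hubs = cx.hub_genes(net, part, "m", k=3)
        assert hubs.iloc[0]["gene"] == "0"
        assert hubs.iloc[0]["score"] == pytest.approx(8.0)

    def test_k_at_least_module_size_returns_whole_module_ranked(self):
        net = two_cliques(size=5)
        part = cx.detect_modules(net)
        label = part.labels[0]
        hubs = cx.hub_genes(net, part, label, k=100)
        assert len(hubs) == 5
        assert (hubs["score"].diff().dropna() <= 1e-12).all()

    def test_tied_scores_broken_lexicographically(self):
        G = nx.Graph()
        G.add_edge("b", "c", weight=0.9)
        G.add_edge("a", "d", weight=0.9)
        net = wrap(G)
        part = cx.ModulePartition(assignment={g: "m" for g in "abcd"})
        hubs = cx.hub_genes(net, part, "m", k=4)
        assert hubs["gene"].tolist() == ["a", "b", "c", "d"]

    def test_unknown_module_and_bad_k_error(self):
        net = two_cliques(size=5)
        part = cx.detect_modules(net)
        with pytest.raises(ValidationError):
            cx.hub_genes(net, part, "nope", k=1)
        with pytest.raises(ValidationError):
            cx.hub_genes(net, part, part.labels[0], k=0)
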