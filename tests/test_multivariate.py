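import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from augbreed.multivariate import (
    correlation_network,
    cut_clusters,
    heatmap_layout,
    pca,
    upgma,
    upgma_from_data,
    zscore,
)

from oracles import brute_force_upgma


def gmat(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"t{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=columns,
                        index=[f"g{i}" for i in range(values.shape[0])])


class TestZscore:
    def test_simple_column(self):
        z = zscore(gmat([[1], [2], [3]]))
        assert list(z.z["t0"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_hand_computed_first_element(self):
        col = [2, 4, 4, 4, 5, 5, 7, 9]
        s = math.sqrt(sum((x - 5) ** 2 for x in col) / 7)
        z = zscore(gmat([[x] for x in col]))
        assert z.z["t0"].iloc[0] == pytest.approx((2 - 5) / s)

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        z = zscore(gmat(rng.normal(3, 7, size=(40, 4)))).z
        assert np.allclose(z.mean(), 0.0, atol=1e-10)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-10)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="t1"):
            zscore(gmat([[1, 5], [2, 5], [3, 5]]))


class TestUpgma:
    def test_identical_rows_merge_first_at_zero(self):
        data = gmat([[1, 1], [1, 1], [5, 9]])
        tree = upgma_from_data(data)
        assert tree.heights[0] == pytest.approx(0.0)
        first = set(tree.linkage[0, :2].astype(int))
        assert first == {0, 1}

    def test_three_point_hand_example(self):
        # d(AB)=2, d(AC)=d(BC)=6: AB merges at 2, C joins at 6
        dist = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0.0]],
            index=list("ABC"), columns=list("ABC"))
        tree = upgma(dist)
        assert tree.heights == pytest.approx([2.0, 6.0])

    @pytest.mark.parametrize("n, seed", [(4, 0), (5, 1), (6, 2), (6, 3)])
    def test_matches_brute_force_average_linkage(self, n, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(n, 3))
        dist = squareform(pdist(points))
        tree = upgma(dist)
        ours = squareform(hierarchy.cophenet(tree.linkage))
        oracle = brute_force_upgma(dist)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_ultrametric_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        tree = upgma_from_data(gmat(rng.normal(size=(12, 3))))
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            upgma(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCutClusters:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(5)
        tree = upgma_from_data(gmat(rng.normal(size=(6, 2))))
        assert cut_clusters(tree, 1).nunique() == 1
        assert cut_clusters(tree, 6).nunique() == 6

    def test_three_point_two_clusters(self):
        dist = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0.0]],
            index=list("ABC"), columns=list("ABC"))
        labels = cut_clusters(upgma(dist), 2)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(6)
        data = gmat(rng.normal(size=(8, 3)))
        perm = data.sample(frac=1.0, random_state=1)
        l1 = cut_clusters(upgma_from_data(data), 3)
        l2 = cut_clusters(upgma_from_data(perm), 3)
        # same partition regardless of label numbering
        groups1 = {frozenset(l1.index[l1 == c]) for c in l1.unique()}
        groups2 = {frozenset(l2.index[l2 == c]) for c in l2.unique()}
        assert groups1 == groups2

    def test_invalid_k(self):
        tree = upgma_from_data(gmat(np.eye(3)))
        with pytest.raises(ValueError):
            cut_clusters(tree, 0)


class TestHeatmapLayout:
    def test_reordering_is_a_permutation(self):
        rng = np.random.default_rng(7)
        data = gmat(rng.normal(size=(9, 4)))
        layout = heatmap_layout(data)
        assert sorted(layout.reordered.index) == sorted(data.index)
        assert sorted(layout.reordered.columns) == sorted(data.columns)
        assert np.allclose(
            np.sort(layout.reordered.to_numpy().ravel()),
            np.sort(data.to_numpy().ravel()))

    def test_planted_groups_are_contiguous(self):
        rng = np.random.default_rng(8)
        up = rng.normal(+3, 0.3, size=(6, 4))
        down = rng.normal(-3, 0.3, size=(6, 4))
        data = gmat(np.vstack([up, down]))
        layout = heatmap_layout(zscore(data))
        order = list(layout.reordered.index)
        group1 = {f"g{i}" for i in range(6)}
        positions = [i for i, g in enumerate(order) if g in group1]
        assert max(positions) - min(positions) == 5  # contiguous block

    def test_single_genotype_degenerates_gracefully(self):
        layout = heatmap_layout(gmat([[1.0, 2.0, 3.0]]))
        assert layout.reordered.shape == (1, 3)


class TestPca:
    def test_two_collinear_traits_one_component(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        data = gmat(np.column_stack([x, 2 * x + 1]))
        result = pca(zscore(data))
        assert result.explained_pct.iloc[0] == pytest.approx(100.0)

    def test_explained_and_contributions_sum_to_100(self):
        rng = np.random.default_rng(10)
        result = pca(zscore(gmat(rng.normal(size=(25, 5)))))
        assert result.explained_pct.sum() == pytest.approx(100.0)
        assert np.allclose(result.contributions.sum(axis=0), 100.0)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(11)
        result = pca(zscore(gmat(rng.normal(size=(25, 4)))))
        v = result.eigenvectors.to_numpy()
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)

    def test_invariant_to_affine_trait_rescaling(self):
        rng = np.random.default_rng(12)
        raw = gmat(rng.normal(size=(20, 3)))
        scaled = raw * np.array([10.0, 0.2, 7.0]) + np.array([5, -3, 100.0])
        r1 = pca(zscore(raw))
        r2 = pca(zscore(scaled))
        assert np.allclose(r1.explained_pct, r2.explained_pct, atol=1e-9)
        assert np.allclose(r1.scores.abs(), r2.scores.abs(), atol=1e-8)

    def test_matches_sklearn_decomposition(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(13)
        z = zscore(gmat(rng.normal(size=(30, 5))))
        ours = pca(z)
        ref = sklearn.PCA()
        ref_scores = ref.fit_transform(z.z.to_numpy())
        assert np.allclose(ours.explained_pct,
                           100 * ref.explained_variance_ratio_, atol=1e-8)
        assert np.allclose(np.abs(ours.scores.to_numpy()),
                           np.abs(ref_scores), atol=1e-8)

    def test_planted_two_factor_structure(self):
        rng = np.random.default_rng(14)
        n = 400
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        noise = rng.normal(scale=0.4, size=(n, 6))
        data = np.column_stack([
            f1 + noise[:, 0], f1 + noise[:, 1], f1 + noise[:, 2],
            f2 + noise[:, 3], f2 + noise[:, 4], f2 + noise[:, 5]])
        result = pca(zscore(gmat(data)))
        # within-block trait correlation is 1/1.16 ~ 0.862, so the two
        # factor components carry 2 * (1 + 2r) / 6 ~ 90.8% of the variance
        share = result.explained_pct.iloc[:2].sum()
        assert share == pytest.approx(90.8, abs=4.0)


class TestCorrelationNetwork:
    def test_duplicated_trait_yields_unit_edge(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=20)
        data = gmat(np.column_stack([x, x, rng.normal(size=20)]))
        net = correlation_network(data)
        assert net.graph.edges["t0", "t1"]["r"] == pytest.approx(1.0)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(16)
        net = correlation_network(gmat(rng.normal(size=(30, 4))))
        corr = net.corr.to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)

    def test_independent_traits_have_small_correlations(self):
        rng = np.random.default_rng(17)
        net = correlation_network(gmat(rng.normal(size=(1000, 5))))
        off = net.corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.15

    def test_threshold_only_affects_display_flag(self):
        rng = np.random.default_rng(18)
        data = gmat(rng.normal(size=(50, 3)))
        loose = correlation_network(data, display_threshold=0.0)
        strict = correlation_network(data, display_threshold=0.99)
        assert loose.graph.number_of_edges() == strict.graph.number_of_edges()
        assert all(d["displayed"] for *_, d in loose.graph.edges(data=True))

    def test_needs_three_genotypes(self):
        with pytest.raises(ValueError):
            correlation_network(gmat([[1, 2], [3, 4.0]]))


class TestFigures:
    def test_figures_written(self, tmp_path):
        rng = np.random.default_rng(19)
        data = gmat(rng.normal(size=(10, 4)))
        z = zscore(data)
        from augbreed.multivariate import plot_biplot, plot_heatmap, plot_network

        plot_heatmap(z, tmp_path / "heat.png")
        result = pca(z)
        plot_biplot(result, tmp_path / "biplot.png")
        plot_network(correlation_network(data), tmp_path / "net.png")
        for name in ("heat.png", "biplot.png", "net.png"):
            assert (tmp_path / name).stat().st_size > 0
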