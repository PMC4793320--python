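import numpy as np
import pandas as pd
import pytest

from ncpart import (ValidationError, build_dendrogram, centroid_distances,
                    cut_dendrogram, fit_group_lda, nest_centroids, to_newick)
from ncpart.nc import DistanceMatrix


def _frame(X, prefix="T"):
    return pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])],
                        index=[f"S{i}" for i in range(X.shape[0])])


def _groups(labels, frame):
    return pd.Series(labels, index=frame.index)


class TestFitGroupLDA:
    def test_axis_aligned_separation(self):
        # symmetric within-group spread makes the scatter exactly diagonal,
        # so the only discriminant axis is the separating coordinate
        cross = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        X = np.vstack([cross, cross + [10.0, 0.0]])
        frame = _frame(X)
        groups = _groups(["a"] * 4 + ["b"] * 4, frame)
        proj = fit_group_lda(frame, groups)
        assert proj.axis_count == 1
        loadings = proj.loadings.to_numpy().ravel()
        assert abs(loadings[1]) < 1e-8 * abs(loadings[0])

    def test_sphering_convention(self):
        rng = np.random.default_rng(1)
        frame = _frame(rng.normal(size=(60, 4)) @ rng.normal(size=(4, 4)))
        groups = _groups(np.repeat([f"g{i}" for i in range(10)], 6), frame)
        proj = fit_group_lda(frame, groups)
        scores = proj.scores.to_numpy()
        centered = scores - pd.DataFrame(scores).groupby(groups.values).transform("mean").to_numpy()
        pooled = centered.T @ centered / (60 - 10)
        assert np.allclose(np.diag(pooled), 1.0, atol=1e-8)

    def test_axis_count_min_g_minus_1(self):
        rng = np.random.default_rng(2)
        frame = _frame(rng.normal(size=(30, 5)))
        groups = _groups(["a"] * 10 + ["b"] * 10 + ["c"] * 10, frame)
        proj = fit_group_lda(frame, groups)
        assert proj.axis_count == 2  # min(G-1=2, p=5)

    def test_insufficient_df_requires_ridge(self):
        rng = np.random.default_rng(3)
        frame = _frame(rng.normal(size=(10, 8)))
        groups = _groups([f"g{i // 2}" for i in range(10)], frame)
        with pytest.raises(ValidationError, match="ridge"):
            fit_group_lda(frame, groups)
        proj = fit_group_lda(frame, groups, ridge=1e-3)
        assert proj.axis_count == 4

    def test_remixing_invariance(self):
        # distances between centroids survive invertible trait remixing
        rng = np.random.default_rng(4)
        frame = _frame(rng.normal(size=(48, 5))
                       + np.repeat(rng.normal(scale=6, size=(8, 5)), 6, axis=0))
        groups = _groups(np.repeat([f"g{i}" for i in range(8)], 6), frame)
        M = rng.normal(size=(5, 5)) + 3 * np.eye(5)
        mixed = _frame(frame.to_numpy() @ M)
        d1 = centroid_distances(nest_centroids(fit_group_lda(frame, groups)))
        d2 = centroid_distances(nest_centroids(fit_group_lda(mixed, groups)))
        assert np.allclose(d1.values, d2.values, atol=1e-6)


class TestNestCentroids:
    def test_singleton_nest(self):
        rng = np.random.default_rng(5)
        frame = _frame(rng.normal(size=(13, 3)))
        groups = _groups(["solo"] + [f"g{i // 4}" for i in range(12)], frame)
        proj = fit_group_lda(frame, groups)
        cents = nest_centroids(proj)
        assert np.allclose(cents.centroids.loc["solo"],
                           proj.scores.iloc[0].to_numpy())
        assert cents.n_individuals["solo"] == 1

    def test_symmetric_pair_at_origin(self):
        scores = pd.DataFrame([[1.0, -2.0], [-1.0, 2.0], [3.0, 3.0]],
                              index=["a", "b", "c"], columns=["LD1", "LD2"])
        from ncpart.nc import LDProjection
        proj = LDProjection(scores, pd.DataFrame(), np.array([]),
                            pd.Series(["N1", "N1", "N2"], index=scores.index))
        cents = nest_centroids(proj)
        assert np.allclose(cents.centroids.loc["N1"], 0.0)

    def test_count_equals_distinct_nests(self, synthetic, analysis_traits):
        table, _ = synthetic
        proj = fit_group_lda(table, traits=analysis_traits)
        cents = nest_centroids(proj)
        assert len(cents) == table.nest_ids.nunique()


class TestCentroidDistances:
    def test_3_4_5(self):
        cents = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        D = centroid_distances(cents)
        assert D.values[0, 1] == pytest.approx(5.0)

    def test_identical_centroids(self):
        cents = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"])
        assert centroid_distances(cents).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        cents = pd.DataFrame(rng.normal(size=(12, 4)),
                             index=[f"n{i}" for i in range(12)])
        D = centroid_distances(cents).values
        X = cents.to_numpy()
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-10)

    def test_relabeling_commutes(self):
        rng = np.random.default_rng(7)
        cents = pd.DataFrame(rng.normal(size=(6, 3)),
                             index=[f"n{i}" for i in range(6)])
        renamed = cents.rename(index=lambda s: "x" + s)
        assert np.allclose(centroid_distances(cents).values,
                           centroid_distances(renamed).values)


class TestDendrogram:
    def test_two_leaves(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        dend = build_dendrogram(D, "average")
        assert dend.merges == [(0, 1)]
        assert dend.heights == [2.0]

    def test_three_equidistant_tie_rule(self):
        D = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        dend = build_dendrogram(D, "average")
        assert dend.merges[0] == (0, 1)          # lexicographically smallest pair
        assert dend.heights[0] == pytest.approx(1.0)
        assert dend.heights[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("linkage", ["ward", "average", "complete"])
    def test_no_height_inversions(self, linkage):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 3))
        D = centroid_distances(pd.DataFrame(X, index=[f"n{i:02d}" for i in range(25)]))
        dend = build_dendrogram(D, linkage)
        assert all(h2 >= h1 - 1e-9 for h1, h2 in zip(dend.heights, dend.heights[1:]))

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(c, 0.1, size=(10, 3))
                       for c in ([0, 0, 0], [10, 0, 0], [0, 10, 0])])
        truth = np.repeat([0, 1, 2], 10)
        D = centroid_distances(pd.DataFrame(X, index=[f"n{i:02d}" for i in range(30)]))
        dend = build_dendrogram(D, "average")
        labels = cut_dendrogram(dend, 3)
        # exhaustive agreement check: same partition as truth
        for i in range(30):
            for j in range(30):
                assert (labels[i] == labels[j]) == (truth[i] == truth[j])

    def test_unsupported_linkage(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError):
            build_dendrogram(D, "median")


class TestNewick:
    def test_two_leaves(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        dend = build_dendrogram(D, "average")
        assert to_newick(dend) == "(a:2,b:2);"

    def test_round_trip_with_dendropy(self):
        import dendropy
        rng = np.random.default_rng(10)
        X = rng.normal(size=(9, 2))
        ids = [f"leaf{i}" for i in range(9)]
        D = centroid_distances(pd.DataFrame(X, index=ids))
        dend = build_dendrogram(D, "average")
        tree = dendropy.Tree.get(data=to_newick(dend), schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == sorted(ids)
        # root-to-leaf path length equals the root merge height for every leaf
        root_height = dend.heights[-1]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height,
                                                              rel=1e-6)

    def test_annotations_joined_by_hyphen(self):
        D = DistanceMatrix(["CASENT001", "CASENT002"],
                           np.array([[0.0, 1.0], [1.0, 0.0]]))
        dend = build_dendrogram(D, "average")
        text = to_newick(dend, annotations={"CASENT001": "exiguus"})
        assert "exiguus-CASENT001" in text

    def test_reserved_characters_quoted(self):
        D = DistanceMatrix(["a b", "c:d"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        dend = build_dendrogram(D, "average")
        text = to_newick(dend)
        assert "'a b'" in text and "'c:d'" in text
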