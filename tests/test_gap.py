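import itertools

import numpy as np
import pytest

from ncpart import (ValidationError, congruence, gap_statistic, part,
                    within_dispersion)
from ncpart.gap import OUTLIER, Partition, _kmeans


class TestWithinDispersion:
    def test_identical_points(self):
        X = np.ones((5, 3))
        assert within_dispersion(X, np.zeros(5)) == 0.0

    def test_two_points_analytic(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert within_dispersion(X, np.zeros(2)) == pytest.approx(25.0 / 2)

    def test_pairwise_form_identity(self):
        # sum_r D_r/(2 n_r) over ordered pairs == sum of squares to centroids
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        labels = rng.integers(0, 4, size=40)
        pairwise = 0.0
        for lab in np.unique(labels):
            sub = X[labels == lab]
            d_r = sum(((a - b) ** 2).sum() for a in sub for b in sub)
            pairwise += d_r / (2 * len(sub))
        assert within_dispersion(X, labels) == pytest.approx(pairwise, abs=1e-10)

    def test_empty_cluster_error(self):
        with pytest.raises(ValidationError):
            within_dispersion(np.ones((0, 2)), np.array([]))


class TestGapStatistic:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        p1 = gap_statistic(X, 4, 20, "hclust", np.random.default_rng(42))
        p2 = gap_statistic(X, 4, 20, "hclust", np.random.default_rng(42))
        assert p1.to_json() == p2.to_json()

    def test_b_equals_1_gives_zero_s(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        prof = gap_statistic(X, 3, 1, "hclust", np.random.default_rng(0))
        assert prof.s == pytest.approx([0.0, 0.0, 0.0])

    def test_kmax_exceeds_rows(self):
        with pytest.raises(ValidationError):
            gap_statistic(np.ones((3, 2)), 4, 5, "hclust", 0)

    def test_b_zero_rejected(self):
        with pytest.raises(ValidationError):
            gap_statistic(np.ones((5, 2)), 2, 0, "hclust", 0)

    def test_single_gaussian_khat_1(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 2))
            prof = gap_statistic(X, 5, 100, "hclust", np.random.default_rng(seed))
            hits += prof.khat == 1
        assert hits >= 18  # >= 90% of seeded runs

    @pytest.mark.parametrize("clusterer", ["hclust", "kmeans"])
    def test_two_far_gaussians_khat_2(self, clusterer):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(60, 2))
            X[:30, 0] += 10.0
            prof = gap_statistic(X, 5, 60, clusterer,
                                 np.random.default_rng(seed))
            hits += prof.khat == 2
        assert hits >= 19  # >= 95%

    def test_se_formula(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 2))
        prof = gap_statistic(X, 3, 40, "hclust", np.random.default_rng(7))
        # s_k = sd_k * sqrt(1 + 1/B) implies s_k >= 0 always
        assert all(s >= 0 for s in prof.s)


class TestKmeans:
    def test_logw_non_increasing_vs_bruteforce(self):
        # brute force over all label assignments of n=7 points
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 2))
        best_w = {}
        for k in range(1, 5):
            best = np.inf
            for assign in itertools.product(range(k), repeat=7):
                if len(set(assign)) != k:
                    continue
                best = min(best, within_dispersion(X, np.array(assign)))
            best_w[k] = best
        # oracle: optimal W_k is non-increasing in k
        assert all(best_w[k] >= best_w[k + 1] - 1e-12 for k in range(1, 4))
        # kmeans with restarts comes within tolerance of the optimum, never below
        for k in range(1, 5):
            labels = _kmeans(X, k, np.random.default_rng(0), n_init=50)
            w = within_dispersion(X, labels)
            assert w >= best_w[k] - 1e-9
            assert w == pytest.approx(best_w[k], rel=1e-6)


class TestPart:
    def test_small_subset_never_split(self):
        # 2*min_size - 1 rows are returned intact even if clearly bimodal
        X = np.vstack([np.zeros((3, 2)), np.full((2, 2), 50.0)])
        p = part(X, min_size=3, B=20, kmax=2, rng=0)
        assert p.n_clusters == 1
        assert len(set(p.labels)) == 1

    def test_single_gaussian_one_cluster_empty_trace(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 2))
        p = part(X, kmax=5, min_size=3, B=60, rng=1)
        assert p.n_clusters == 1
        assert p.trace == []

    @pytest.mark.parametrize("clusterer", ["hclust", "kmeans"])
    def test_three_separated_gaussians(self, clusterer):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(c, 1.0, size=(20, 2))
                       for c in ([0, 0], [12, 0], [0, 12])])
        truth = np.repeat([1, 2, 3], 20)
        p = part(X, kmax=6, min_size=3, B=60, clusterer=clusterer, rng=2)
        assert p.n_clusters == 3
        labels = np.array(p.labels)
        for i in range(60):
            for j in range(60):
                assert (labels[i] == labels[j]) == (truth[i] == truth[j])

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(c, 0.5, size=(15, 2))
                       for c in ([0, 0], [10, 0])])
        ids = [f"i{i:02d}" for i in range(30)]
        p1 = part(X, ids=ids, kmax=4, min_size=3, B=40, rng=3)
        perm = rng.permutation(30)
        p2 = part(X[perm], ids=[ids[i] for i in perm], kmax=4, min_size=3,
                  B=40, rng=3)
        cong = congruence(p1, p2)
        assert cong.wildcard_ids == []

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 2))
        p1 = part(X, kmax=4, min_size=3, B=30, rng=9)
        p2 = part(X, kmax=4, min_size=3, B=30, rng=9)
        assert p1.labels == p2.labels and p1.trace == p2.trace

    def test_outlier_labeling(self):
        # two big blobs and one lone distant point -> OUTLIER
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal([0, 0], 0.5, size=(10, 2)),
                       rng.normal([10, 0], 0.5, size=(10, 2)),
                       [[100.0, 100.0], [101.0, 101.0]]])
        p = part(X, kmax=5, min_size=3, B=40, rng=4)
        assert p.labels[-1] == OUTLIER and p.labels[-2] == OUTLIER
        assert p.n_clusters == 2

    def test_labels_renumbered_in_first_appearance_order(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal([0, 0], 0.5, size=(8, 2)),
                       rng.normal([15, 0], 0.5, size=(8, 2))])
        p = part(X, kmax=3, min_size=3, B=40, rng=5)
        assert p.labels[0] == 1 and p.labels[-1] == 2


class TestCongruence:
    def _partition(self, ids, labels, tag="part-hclust"):
        return Partition(list(ids), list(labels), tag, 3)

    def test_permuted_labels_zero_wildcards(self):
        ids = list("abcdef")
        p1 = self._partition(ids, [1, 1, 2, 2, 3, 3])
        p2 = self._partition(ids, [3, 3, 1, 1, 2, 2], "part-kmeans")
        cong = congruence(p1, p2)
        assert cong.wildcard_ids == []
        assert cong.mapping == {1: 2, 2: 3, 3: 1}

    def test_single_moved_id_is_wildcard(self):
        ids = list("abcdef")
        p1 = self._partition(ids, [1, 1, 1, 2, 2, 2])
        p2 = self._partition(ids, [1, 1, 2, 2, 2, 2])
        cong = congruence(p1, p2)
        assert cong.wildcard_ids == ["c"]

    def test_outlier_in_one_partition_is_wildcard(self):
        ids = list("abcdef")
        p1 = self._partition(ids, [1, 1, 1, 2, 2, OUTLIER])
        p2 = self._partition(ids, [1, 1, 1, 2, 2, 2])
        cong = congruence(p1, p2)
        assert cong.wildcard_ids == ["f"]

    def test_congruent_and_wildcard_partition_all_ids(self):
        ids = list("abcdefgh")
        rng = np.random.default_rng(11)
        p1 = self._partition(ids, rng.integers(1, 3, 8).tolist())
        p2 = self._partition(ids, rng.integers(1, 3, 8).tolist())
        cong = congruence(p1, p2)
        assert sorted(cong.congruent_ids + cong.wildcard_ids) == sorted(ids)
        assert not set(cong.congruent_ids) & set(cong.wildcard_ids)

    def test_id_mismatch(self):
        p1 = self._partition(["a", "b"], [1, 1])
        p2 = self._partition(["a", "c"], [1, 1])
        with pytest.raises(ValidationError):
            congruence(p1, p2)
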