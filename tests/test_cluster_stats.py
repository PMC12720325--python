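import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from _oracles import separation_oracle, ward_oracle
from conftest import make_matrix
from hrepipe.cluster_stats import (
    ClusterConfig,
    cluster_mean_profiles,
    cut_dendrogram,
    exhaustive_permutation_test,
    hierarchical_cluster,
    permutation_test,
    separation_statistic,
)
from hrepipe.core_io import Condition, Genotype


def dmat(points):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    return squareform(pdist(pts))


FOUR_POINTS = dmat([0.0, 1.0, 10.0, 11.0])
LABELS_22 = np.array(["A", "A", "B", "B"])


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        d = hierarchical_cluster(X)
        assert d.heights[0] == 0.0

    def test_two_tight_pairs_topology(self):
        X = np.array([[0.0], [0.1], [100.0], [100.1]])
        d = hierarchical_cluster(X)
        merges = d.merge_sequence()
        assert {frozenset([0, 1]), frozenset([2, 3])} == {
            m[0] | m[1] for m in merges[:2]
        }
        assert merges[2][0] | merges[2][1] == frozenset(range(4))

    @pytest.mark.parametrize("method", ["ward_d", "ward_d2"])
    def test_six_point_fixture_matches_naive_oracle(self, method):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(6, 3))
        d = hierarchical_cluster(X, ClusterConfig(linkage=method))
        expected = ward_oracle(X, method)
        got = d.merge_sequence()
        assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in expected]
        np.testing.assert_allclose(
            [h for _, _, h in got], [h for _, _, h in expected], rtol=1e-9
        )

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4))
        for method in ("ward_d", "ward_d2"):
            d = hierarchical_cluster(X, ClusterConfig(linkage=method))
            assert (np.diff(d.heights) >= -1e-12).all()

    def test_nan_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="drop_na_rows"):
            hierarchical_cluster(X)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[1.0, 2.0]]))

    def test_standardize_rows_flag(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 5))
        plain = hierarchical_cluster(X, ClusterConfig())
        scaled = hierarchical_cluster(X, ClusterConfig(standardize_rows=True))
        assert not np.allclose(plain.heights, scaled.heights)


class TestCut:
    def test_cut_above_root(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        d = hierarchical_cluster(X)
        assignment = cut_dendrogram(d, height=float(d.heights[-1]) + 1)
        assert assignment.n_clusters == 1

    def test_cut_below_all_merges(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        d = hierarchical_cluster(X)
        assignment = cut_dendrogram(d, height=float(d.heights[0]) / 2)
        assert assignment.n_clusters == 5

    def test_two_blob_recovery_with_k(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.3, (6, 3)), rng.normal(10, 0.3, (7, 3))])
        assignment = cut_dendrogram(hierarchical_cluster(X), k=2)
        labels = assignment.labels
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_exactly_one_mode_required(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        d = hierarchical_cluster(X)
        with pytest.raises(ValueError):
            cut_dendrogram(d)
        with pytest.raises(ValueError):
            cut_dendrogram(d, height=1.0, k=2)

    def test_labels_contiguous_from_one(self):
        X = np.random.default_rng(1).normal(size=(9, 2))
        assignment = cut_dendrogram(hierarchical_cluster(X), k=4)
        assert sorted(set(assignment.labels.tolist())) == [1, 2, 3, 4]


class TestSeparationStatistic:
    def test_forced_construction(self):
        d = dmat([0.0, 0.0, 10.0, 10.0])
        assert separation_statistic(d, LABELS_22) == pytest.approx(10.0)

    def test_all_identical_points(self):
        d = np.zeros((4, 4))
        assert separation_statistic(d, LABELS_22) == 0.0

    def test_pairwise_enumeration_oracle(self):
        # between mean (10+11+9+10)/4 = 10, within mean 1 -> 9
        assert separation_statistic(FOUR_POINTS, LABELS_22) == pytest.approx(9.0)
        assert separation_oracle(
            np.array([0.0, 1.0, 10.0, 11.0]), LABELS_22
        ) == pytest.approx(9.0)

    def test_all_singletons_error(self):
        with pytest.raises(ValueError, match="singleton"):
            separation_statistic(dmat([0.0, 5.0]), ["A", "B"])

    def test_one_cluster_error(self):
        with pytest.raises(ValueError):
            separation_statistic(FOUR_POINTS, ["A", "A", "A", "A"])

    def test_asymmetric_matrix_error(self):
        d = FOUR_POINTS.copy()
        d[0, 1] += 1
        with pytest.raises(ValueError, match="symmetric"):
            separation_statistic(d, LABELS_22)

    def test_relabel_and_reorder_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 2))
        labels = np.array(["A", "A", "A", "B", "B", "C", "C", "C"])
        d = squareform(pdist(pts))
        base = separation_statistic(d, labels)
        swap = {"A": "C", "B": "A", "C": "B"}
        assert separation_statistic(d, [swap[l] for l in labels]) == pytest.approx(base)
        perm = rng.permutation(8)
        assert separation_statistic(d[np.ix_(perm, perm)], labels[perm]) == pytest.approx(
            base
        )


class TestPermutationTest:
    def test_identical_points_p_one(self):
        d = np.zeros((4, 4))
        result = permutation_test(d, LABELS_22, n_permutations=99, seed=0)
        assert result.p_value == 1.0

    def test_seed_determinism(self):
        r1 = permutation_test(FOUR_POINTS, LABELS_22, n_permutations=999, seed=5)
        r2 = permutation_test(FOUR_POINTS, LABELS_22, n_permutations=999, seed=5)
        assert r1 == r2

    def test_p_counts_consistent(self):
        r = permutation_test(FOUR_POINTS, LABELS_22, n_permutations=999, seed=1)
        assert r.p_value == r.n_at_least_as_extreme / 999

    def test_add_one_mode(self):
        r = permutation_test(
            FOUR_POINTS, LABELS_22, n_permutations=99, seed=1, add_one=True
        )
        assert r.p_value == (r.n_at_least_as_extreme + 1) / 100

    def test_converges_to_exhaustive(self):
        r = permutation_test(FOUR_POINTS, LABELS_22, n_permutations=9999, seed=3)
        exact = 1.0 / 3.0
        sd = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(r.p_value - exact) <= 3 * sd


class TestExhaustive:
    def test_four_point_fixture(self):
        r = exhaustive_permutation_test(FOUR_POINTS, LABELS_22)
        assert r.n_permutations == 6
        assert r.n_at_least_as_extreme == 2  # observed split and its mirror
        assert r.p_value == pytest.approx(1 / 3)

    def test_two_singletons_rejected(self):
        with pytest.raises(ValueError):
            exhaustive_permutation_test(dmat([0.0, 5.0]), ["A", "B"])

    def test_unique_maximum_gives_symmetry_count(self):
        # distinct group sizes: no label-swap symmetry, so a strict unique
        # maximum yields p = 1/total
        pts = np.array([0.0, 0.2, 0.4, 9.0, 9.1])
        labels = ["A", "A", "A", "B", "B"]
        r = exhaustive_permutation_test(dmat(pts), labels)
        assert r.n_permutations == 10
        assert r.n_at_least_as_extreme == 1
        assert r.p_value == pytest.approx(1 / 10)

    def test_limit_enforced(self):
        d = np.zeros((30, 30))
        labels = ["A"] * 15 + ["B"] * 15
        with pytest.raises(ValueError, match="exceed"):
            exhaustive_permutation_test(d, labels, max_arrangements=1000)


class TestMeanProfiles:
    def design(self):
        out = []
        for gt in (Genotype.WT, Genotype.KO):
            for tp in (0.0, 4.0, 24.0):
                out.append((gt, Condition.LPS, tp))
        return out

    def test_single_gene_cluster_is_its_trajectory(self):
        values = np.array([[1.0, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0]])
        m = make_matrix(values, design=self.design())
        from hrepipe.cluster_stats import ClusterAssignment

        assignment = ClusterAssignment(["g0", "g1"], np.array([1, 2]))
        profiles = cluster_mean_profiles(m, assignment)
        for tp, wt_val, ko_val in [(0.0, 1, 4), (4.0, 2, 5), (24.0, 3, 6)]:
            assert profiles.loc[1, ("WT", "LPS", tp)] == wt_val
            assert profiles.loc[1, ("KO", "LPS", tp)] == ko_val

    def test_opposite_genes_average_to_zero(self):
        v = np.array([[1.0, 2, 3, 4, 5, 6]])
        values = np.vstack([v, -v])
        m = make_matrix(values, design=self.design())
        from hrepipe.cluster_stats import ClusterAssignment

        assignment = ClusterAssignment(["g0", "g1"], np.array([1, 1]))
        profiles = cluster_mean_profiles(m, assignment)
        np.testing.assert_allclose(profiles.loc[1].to_numpy(), np.zeros(6))

    def test_planted_clusters_separate(self, noise_free_dataset):
        ds = noise_free_dataset
        truth = ds.truth
        genes = [g for g in truth.gene_ids if truth.cluster[g] in (1, 2)]
        from hrepipe.cluster_stats import ClusterAssignment

        assignment = ClusterAssignment(
            genes, np.array([truth.cluster[g] for g in genes])
        )
        m = ds.expression.subset_genes(genes).select_samples(condition=Condition.LPS)
        profiles = cluster_mean_profiles(m, assignment)
        wt24_resp = profiles.loc[1, ("WT", "LPS", 24.0)]
        ko24_resp = profiles.loc[1, ("KO", "LPS", 24.0)]
        wt24_unresp = profiles.loc[2, ("WT", "LPS", 24.0)]
        ko24_unresp = profiles.loc[2, ("KO", "LPS", 24.0)]
        # responsive cluster: WT-KO gap equals the planted effect; shared
        # induction cluster: no genotype gap
        resp_gap = wt24_resp - ko24_resp
        unresp_gap = wt24_unresp - ko24_unresp
        assert resp_gap == pytest.approx(ds.config.effect_log2fc)
        assert unresp_gap == pytest.approx(0.0)
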