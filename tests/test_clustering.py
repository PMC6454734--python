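"""Distance metrics, PAM, silhouette, k selection and hierarchical trees."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from cometa import (
    co_clustering_report,
    hclust_discrete,
    pam,
    profile_distance_matrix,
    select_k,
    silhouette,
)


def dist_from_points(pts, labels):
    return pd.DataFrame(cdist(pts, pts), index=labels, columns=labels)


def blobs(centers, per_blob, spread, seed=0):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for bi, c in enumerate(centers):
        for j in range(per_blob):
            pts.append(rng.normal(c, spread, size=2))
            labels.append(f"b{bi}_{j}")
    return dist_from_points(np.array(pts), labels)


def brute_force_pam_cost(d: pd.DataFrame, k: int) -> float:
    return min(
        d.loc[:, list(meds)].min(axis=1).sum()
        for meds in itertools.combinations(d.index, k)
    )


class TestDistances:
    def test_identical_profiles_zero_distance(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        d = profile_distance_matrix(m, "correlation")
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_negated_profiles_correlation_distance_two(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [-1.0, -2, -3]})
        assert profile_distance_matrix(m, "correlation").loc["a", "b"] == pytest.approx(2.0)

    def test_discrete_hand_counts(self):
        m = pd.DataFrame({"a": [1, 0, -1], "b": [1, 0, 1]})
        assert profile_distance_matrix(m, "hamming").loc["a", "b"] == pytest.approx(1 / 3)
        assert profile_distance_matrix(m, "matching").loc["a", "b"] == pytest.approx(1 / 2)
        assert profile_distance_matrix(m, "manhattan").loc["a", "b"] == pytest.approx(2.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.choice([-1, 0, 1], size=(20, 4)), columns=list("wxyz"))
        d = profile_distance_matrix(m, "hamming")
        np.testing.assert_allclose(d, d.T)
        assert (np.diag(d) == 0).all()

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            profile_distance_matrix(pd.DataFrame({"a": [1.0, 2]}), "correlation")


class TestPam:
    def test_two_planted_blobs_recovered(self):
        d = blobs([(0, 0), (10, 10)], 5, 0.3, seed=1)
        res = pam(d, 2)
        groups = {}
        for item, med in res.assignment.items():
            groups.setdefault(med, set()).add(item.split("_")[0])
        assert all(len(g) == 1 for g in groups.values())

    @pytest.mark.parametrize("n,k", [(6, 2), (7, 3), (8, 2), (8, 4)])
    def test_cost_matches_exhaustive_search(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        pts = rng.normal(size=(n, 2))
        d = dist_from_points(pts, [f"i{j}" for j in range(n)])
        res = pam(d, k)
        assert res.total_cost == pytest.approx(brute_force_pam_cost(d, k), abs=1e-9)

    def test_k_n_minus_one_cost_is_min_pairwise_distance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        d = dist_from_points(pts, list("abcdef"))
        res = pam(d, 5)
        off_diag = d.to_numpy()[~np.eye(6, dtype=bool)]
        assert res.total_cost == pytest.approx(off_diag.min())

    def test_medoids_assigned_to_themselves(self):
        d = blobs([(0, 0), (5, 5), (9, 0)], 4, 0.5, seed=2)
        res = pam(d, 3)
        for m in res.medoids:
            assert res.assignment[m] == m

    def test_invalid_k_rejected(self):
        d = blobs([(0, 0)], 4, 0.5)
        with pytest.raises(ValueError):
            pam(d, 1)
        with pytest.raises(ValueError):
            pam(d, 4)


class TestSilhouette:
    def test_tight_distant_blobs_near_one(self):
        d = blobs([(0, 0), (50, 50)], 6, 0.1, seed=3)
        res = pam(d, 2)
        _, avg = silhouette(d, res.assignment)
        assert avg > 0.9

    def test_equidistant_items_near_zero(self):
        n = 6
        d = pd.DataFrame(1.0 - np.eye(n), index=list("abcdef"), columns=list("abcdef"))
        assignment = {x: ("a" if x in "abc" else "d") for x in "abcdef"}
        _, avg = silhouette(d, assignment)
        assert avg == pytest.approx(0.0)

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(15, 3))
        labels = [f"i{j}" for j in range(15)]
        d = dist_from_points(pts, labels)
        res = pam(d, 3)
        per_item, avg = silhouette(d, res.assignment)
        codes = [sorted(res.medoids).index(res.assignment[x]) for x in labels]
        expected = silhouette_score(d.to_numpy(), codes, metric="precomputed")
        assert avg == pytest.approx(expected, abs=1e-10)

    def test_relabeling_and_scaling_invariance(self):
        d = blobs([(0, 0), (4, 4), (8, 0)], 4, 0.4, seed=8)
        res = pam(d, 3)
        _, avg1 = silhouette(d, res.assignment)
        _, avg2 = silhouette(d * 13.7, res.assignment)
        assert avg1 == pytest.approx(avg2)

    def test_single_cluster_rejected(self):
        d = blobs([(0, 0)], 4, 0.5)
        with pytest.raises(ValueError):
            silhouette(d, dict.fromkeys(d.index, "c0"))


class TestSelectK:
    def test_three_planted_blobs_select_three(self):
        d = blobs([(0, 0), (10, 0), (5, 9)], 5, 0.4, seed=9)
        best, results = select_k(d, range(2, 6))
        assert best == 3
        assert set(results) == {2, 3, 4, 5}

    def test_all_identical_items_tie_selects_smallest_k(self):
        n = 5
        d = pd.DataFrame(np.zeros((n, n)), index=list("abcde"), columns=list("abcde"))
        best, _ = select_k(d, range(2, 5))
        assert best == 2

    def test_range_of_one_returns_it(self):
        d = blobs([(0, 0), (9, 9)], 4, 0.3, seed=10)
        best, results = select_k(d, [3])
        assert best == 3 and list(results) == [3]


class TestHclustDiscrete:
    def test_duplicate_columns_merge_first_at_zero_height(self):
        rng = np.random.default_rng(11)
        col = rng.choice([-1, 0, 1], 30)
        m = pd.DataFrame({"u": col, "v": col, "w": rng.choice([-1, 0, 1], 30)})
        res = hclust_discrete(m, "hamming")
        assert set(res.first_pair) == {"u", "v"}
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_close_column_joins_reference_before_distant_one(self):
        rng = np.random.default_rng(12)
        ref = rng.choice([-1, 0, 1], 200)
        close, far = ref.copy(), ref.copy()
        flip = rng.permutation(200)
        for i in flip[:20]:
            close[i] = -1 if close[i] != -1 else 1   # 90% identical
        for i in flip[:100]:
            far[i] = -1 if far[i] != -1 else 1       # 50% identical
        m = pd.DataFrame({"ref": ref, "close": close, "far": far})
        report = co_clustering_report(m, "ref")
        assert (report["partners"] == "close").all()

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.choice([-1, 0, 1], size=(50, 6)),
                         columns=list("abcdef"))
        res = hclust_discrete(m, "manhattan")
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()

    def test_average_linkage_matches_hand_computation(self):
        # four columns with hamming distances engineered so the merge order
        # and average-linkage heights can be verified by hand:
        # d(a,b)=0.1, d(c,d)=0.2, cross distances all 0.8
        a = np.zeros(40)
        b = a.copy(); b[:4] = 1                      # 4/40 = 0.1
        c = np.full(40, -1.0); d = c.copy(); d[:8] = 1   # 8/40 = 0.2
        m = pd.DataFrame({"a": a, "b": b, "c": c, "d": d}).astype(int)
        dist = profile_distance_matrix(m, "hamming")
        assert dist.loc["a", "b"] == pytest.approx(0.1)
        assert dist.loc["c", "d"] == pytest.approx(0.2)
        res = hclust_discrete(m, "hamming")
        heights = res.linkage[:, 2]
        assert set(res.first_pair) == {"a", "b"}
        assert heights[0] == pytest.approx(0.1)
        assert heights[1] == pytest.approx(0.2)
        # final merge: average of the four cross distances
        cross = [dist.loc[x, y] for x in "ab" for y in "cd"]
        assert heights[2] == pytest.approx(np.mean(cross))
        assert res.newick().count("(") == 3

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            hclust_discrete(pd.DataFrame({"a": [2, 0], "b": [0, 1]}), "hamming")
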