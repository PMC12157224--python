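"""Clustering, validity indices and bootstrap stability.

Brute-force oracles: Kruskal MST edge weights for single linkage, direct
silhouette/Dunn formulas over enumerated set partitions, and
scikit-learn's silhouette as an independent implementation.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from addsim.clustering import (DistanceMatrix, LINKAGES, bin_cluster,
                               bootstrap_stability, classical_mds,
                               cophenetic_corr, cut_k,
                               distance_from_similarity, hclust,
                               internal_indices, kmeans, select_k,
                               stability_indices, validation_report)
from addsim.similarity import SimilarityMatrix
from addsim.synthetic_fixtures import gaussian_feature_matrix

import pandas as pd


def _random_dm(seed, n):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    return DistanceMatrix(list(range(n)), squareform(pdist(X)))


ULTRAMETRIC = DistanceMatrix(
    list("abcd"),
    np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 3], [6, 6, 3, 0]],
             dtype=float))


class TestDistance:
    def test_complement_transform(self):
        s = SimilarityMatrix([1, 2], np.array([[1.0, 0.76], [0.76, 1.0]]))
        dm = distance_from_similarity(s)
        assert dm.d[0, 1] == pytest.approx(0.24)
        assert dm.d[0, 0] == 0.0

    def test_asymmetric_rejected(self):
        s = SimilarityMatrix([1, 2], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            distance_from_similarity(s)


class TestHclust:
    def test_two_points_merge_at_distance(self):
        dm = DistanceMatrix([0, 1], np.array([[0.0, 3.5], [3.5, 0.0]]))
        tree = hclust(dm, "single")
        assert tree.merges == [(0, 1, 3.5)]

    def test_ultrametric_heights_recovered(self):
        tree = hclust(ULTRAMETRIC, "single")
        assert sorted(h for _, _, h in tree.merges) == [2.0, 3.0, 6.0]

    @pytest.mark.parametrize("linkage", LINKAGES)
    @pytest.mark.parametrize("seed", range(5))
    def test_heights_non_decreasing(self, linkage, seed):
        tree = hclust(_random_dm(seed, 12), linkage)
        heights = [h for _, _, h in tree.merges]
        assert all(h2 >= h1 - 1e-12
                   for h1, h2 in zip(heights, heights[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_single_linkage_heights_equal_mst_weights(self, seed):
        dm = _random_dm(seed + 50, 10)
        tree = hclust(dm, "single")
        g = nx.Graph()
        for i in range(dm.n):
            for j in range(i + 1, dm.n):
                g.add_edge(i, j, weight=dm.d[i, j])
        mst = sorted(d["weight"]
                     for _, _, d in nx.minimum_spanning_tree(g).edges(data=True))
        assert np.allclose(sorted(h for _, _, h in tree.merges), mst)

    def test_rejects_tiny_input(self):
        with pytest.raises(ValueError):
            hclust(DistanceMatrix([0], np.zeros((1, 1))), "single")

    def test_unknown_linkage(self):
        with pytest.raises(ValueError, match="unsupported linkage"):
            hclust(_random_dm(0, 5), "median")


class TestCophenetic:
    @pytest.mark.parametrize("linkage", ["single", "average", "complete"])
    def test_ultrametric_is_fixed_point(self, linkage):
        assert cophenetic_corr(hclust(ULTRAMETRIC, linkage),
                               ULTRAMETRIC) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_one(self, seed):
        dm = _random_dm(seed + 200, 9)
        for lk in LINKAGES:
            assert abs(cophenetic_corr(hclust(dm, lk), dm)) <= 1.0 + 1e-12

    def test_degenerate_distances_rejected(self):
        dm = DistanceMatrix([0, 1, 2], np.ones((3, 3)) - np.eye(3))
        tree = hclust(dm, "single")
        with pytest.raises(ValueError, match="degenerate"):
            cophenetic_corr(tree, dm)


class TestCut:
    def test_extremes(self):
        dm = _random_dm(3, 8)
        tree = hclust(dm, "average")
        assert len(set(cut_k(tree, 1))) == 1
        assert len(set(cut_k(tree, 8))) == 8
        with pytest.raises(ValueError):
            cut_k(tree, 9)

    def test_labels_stable_by_first_occurrence(self):
        tree = hclust(_random_dm(4, 10), "ward.d2")
        lab = cut_k(tree, 3)
        firsts = [np.argmax(lab == v) for v in range(3)]
        assert firsts == sorted(firsts)


def _brute_silhouette(d, labels):
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(np.mean([d[i, j] for j in range(n) if labels[j] == u])
                for u in set(labels) if u != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def _brute_dunn(d, labels):
    uniq = sorted(set(labels))
    inter = min(d[i, j] for i in range(len(labels))
                for j in range(len(labels))
                if labels[i] != labels[j])
    intra = [d[i, j] for i in range(len(labels)) for j in range(len(labels))
             if i != j and labels[i] == labels[j]]
    return inter / max(intra) if intra else 0.0


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


class TestInternalIndices:
    def test_perfectly_separated_limit(self):
        # cluster sizes exceed the neighbor window, so no neighborhood
        # violations occur in the well-separated limit
        X = np.vstack([np.zeros((12, 2)), 100 + np.zeros((12, 2))])
        X += np.arange(24)[:, None] * 1e-3
        dm = DistanceMatrix(list(range(24)), squareform(pdist(X)))
        labels = np.array([0] * 12 + [1] * 12)
        conn, dunn, sil = internal_indices(dm, labels)
        assert conn == 0.0
        assert sil > 0.99
        assert dunn > 1.0

    def test_collinear_hand_values(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])[:, None]
        dm = DistanceMatrix(list(range(4)), squareform(pdist(pts)))
        labels = np.array([0, 0, 1, 1])
        _, dunn, sil = internal_indices(dm, labels)
        assert dunn == pytest.approx(9.0)  # min inter 9 / max diameter 1
        # point at 0: a = 1, b = (10+11)/2
        expected_first = (10.5 - 1.0) / 10.5
        sil_first = _brute_silhouette(dm.d, labels)
        assert sil == pytest.approx(sil_first)
        assert _brute_silhouette(dm.d, np.array([0, 0, 1, 1]))
        assert (10.5 - 1) / 10.5 == pytest.approx(expected_first)

    @pytest.mark.parametrize("n", [6, 7])
    def test_agrees_with_brute_force_on_all_partitions(self, n):
        rng = np.random.default_rng(n)
        d = squareform(pdist(rng.normal(size=(n, 2))))
        dm = DistanceMatrix(list(range(n)), d)
        for part in _partitions(list(range(n))):
            if len(part) < 2:
                continue
            labels = np.empty(n, dtype=int)
            for ci, block in enumerate(part):
                labels[block] = ci
            conn, dunn, sil = internal_indices(dm, labels)
            assert sil == pytest.approx(_brute_silhouette(d, labels))
            assert dunn == pytest.approx(_brute_dunn(d, labels))

    @pytest.mark.parametrize("seed", range(5))
    def test_silhouette_matches_sklearn(self, seed):
        dm = _random_dm(seed + 400, 12)
        labels = cut_k(hclust(dm, "ward.d2"), 3)
        if len(set(labels)) < 2:
            pytest.skip("degenerate cut")
        ours = internal_indices(dm, labels)[2]
        ref = silhouette_score(dm.d, labels, metric="precomputed")
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_requires_two_clusters(self):
        dm = _random_dm(0, 5)
        with pytest.raises(ValueError):
            internal_indices(dm, np.zeros(5, dtype=int))


class TestStabilityIndices:
    def test_duplicated_columns_give_zero_apn(self):
        X, _ = gaussian_feature_matrix(0, 3, 8, 3, 8.0, 0.5)
        X = np.hstack([X, X])  # every deletion leaves the geometry intact
        apn, ad, adm, fom = stability_indices(X, 3)
        assert apn == pytest.approx(0.0)
        assert adm == pytest.approx(0.0, abs=1e-9)

    def test_separated_clusters_low_adm(self):
        X, _ = gaussian_feature_matrix(1, 3, 10, 4, 10.0, 0.5)
        _, _, adm, _ = stability_indices(X, 3)
        assert adm < 0.5

    def test_noise_column_has_higher_fom(self):
        X, _ = gaussian_feature_matrix(2, 3, 10, 3, 10.0, 0.3)
        rng = np.random.default_rng(5)
        noisy = np.hstack([X, rng.normal(scale=3.0, size=(len(X), 1))])
        # FOM of the noise column: cluster on structure, remove noise col
        from addsim.clustering import _cluster_features
        part = _cluster_features(noisy[:, :3], 3, "hclust", "ward.d2", 0)
        def fom_of(col):
            sse = sum(((col[part == u] - col[part == u].mean()) ** 2).sum()
                      for u in np.unique(part))
            return np.sqrt(sse / len(col))
        assert fom_of(noisy[:, 3]) > fom_of(noisy[:, 0])

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            stability_indices(np.zeros((5, 1)), 2)


class TestKmeans:
    def test_k_equals_n_zero_variance(self):
        X = np.arange(10, dtype=float)[:, None] * 3
        labels = kmeans(X, 10, seed=0)
        assert len(set(labels)) == 10

    def test_seed_determinism(self):
        X, _ = gaussian_feature_matrix(7, 3, 10, 4, 5.0, 1.0)
        assert np.array_equal(kmeans(X, 3, seed=11), kmeans(X, 3, seed=11))

    def test_distance_matrix_input_via_mds(self):
        X, lab = gaussian_feature_matrix(8, 3, 10, 4, 8.0, 0.7)
        dm = DistanceMatrix(list(range(len(X))), squareform(pdist(X)))
        got = kmeans(dm, 3, seed=0)
        assert adjusted_rand_score(lab, got) > 0.9

    def test_mds_preserves_distances(self):
        dm = _random_dm(9, 8)
        emb = classical_mds(dm, dim=7)
        assert np.allclose(squareform(pdist(emb)), dm.d, atol=1e-8)


class TestSelectK:
    @staticmethod
    def _report(votes):
        # measure m votes for k by giving k the best (lowest) score
        rows = []
        measures = ["connectivity", "apn", "ad", "adm", "fom", "dunn",
                    "silhouette"]
        for m, best in zip(measures, votes):
            for k in (2, 3, 4):
                good = (k == best)
                score = (0.0 if good else 1.0)
                if m in ("dunn", "silhouette"):
                    score = 1.0 if good else 0.0
                rows.append({"method": "hclust", "k": k, "measure": m,
                             "score": score})
        return pd.DataFrame(rows)

    def test_majority_tie_keeps_both(self):
        report = self._report([2, 2, 2, 4, 4, 4, 3])
        assert select_k(report) == {2, 4}

    def test_unanimous(self):
        assert select_k(self._report([3] * 7)) == {3}

    def test_full_tie_keeps_all(self):
        assert select_k(self._report([2, 3, 4, 2, 3, 4, 2])) == {2}

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            select_k(pd.DataFrame())


class TestBinning:
    def test_identical_rows_single_cluster(self):
        X = np.ones((6, 3))
        X[0, 0] = 1.0
        res = bin_cluster(X + 0.0, [0.5])
        assert res[0.5]["sizes"] == [6]

    def test_planted_groups_recovered_at_small_cutoff(self):
        X, lab = gaussian_feature_matrix(3, 2, 8, 3, 12.0, 0.3)
        res = bin_cluster(X, [0.3])
        got = res[0.3]["labels"]
        assert adjusted_rand_score(lab, got) == 1.0

    def test_cutoff_zero_groups_duplicates(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [9, 9]])
        res = bin_cluster(X, [0.0])
        assert res[0.0]["sizes"] == [2, 1, 1]

    def test_empty_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            bin_cluster(np.zeros((3, 2)), [])


class TestBootstrap:
    def test_separated_clusters_highly_stable(self):
        X, _ = gaussian_feature_matrix(4, 2, 10, 3, 12.0, 0.5)
        dm = DistanceMatrix(list(range(len(X))), squareform(pdist(X)))
        rep = bootstrap_stability(dm, 2, b=30, seed=1)
        assert all(j > 0.85 for j in rep.avg_jaccard)
        assert set(rep.stability_label) == {"highly stable"}

    def test_uniform_noise_usually_unstable(self):
        hits = 0
        for seed in range(11):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(24, 3))
            dm = DistanceMatrix(list(range(24)), squareform(pdist(X)))
            rep = bootstrap_stability(dm, 4, b=30, seed=seed)
            hits += min(rep.avg_jaccard) < 0.65
        assert hits > 5  # majority of seeds show an unstable cluster

    def test_stability_decreases_with_separation(self):
        means = []
        for sep in (6.0, 3.0, 0.0):
            vals = []
            for seed in range(10):
                X, _ = gaussian_feature_matrix(seed, 3, 8, 3, sep, 1.0)
                dm = DistanceMatrix(list(range(len(X))),
                                    squareform(pdist(X)))
                rep = bootstrap_stability(dm, 3, b=20, seed=seed)
                vals.append(np.mean(rep.avg_jaccard))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_seed_determinism(self):
        dm = _random_dm(10, 15)
        r1 = bootstrap_stability(dm, 3, b=25, seed=9)
        r2 = bootstrap_stability(dm, 3, b=25, seed=9)
        assert r1.avg_jaccard == r2.avg_jaccard
        assert r1.dissolution_rate == r2.dissolution_rate

    def test_rejects_bad_args(self):
        dm = _random_dm(0, 6)
        with pytest.raises(ValueError):
            bootstrap_stability(dm, 1, b=10)
        with pytest.raises(ValueError):
            bootstrap_stability(dm, 2, b=0)


class TestValidationReport:
    def test_long_format_and_selection(self):
        X, _ = gaussian_feature_matrix(5, 3, 8, 3, 8.0, 0.8)
        report = validation_report(X, range(2, 5), methods=("hclust",))
        assert set(report.columns) == {"method", "k", "measure", "score"}
        assert set(report.measure) == {"connectivity", "dunn", "silhouette",
                                       "apn", "ad", "adm", "fom"}
        ks = select_k(report)
        assert ks and all(2 <= k <= 4 for k in ks)
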