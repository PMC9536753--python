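import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from regnetrank import clustering as gc
from regnetrank.synthetic import make_wave_matrix


class TestPcaReduce:
    def test_exact_low_rank(self, rng):
        basis = rng.normal(size=(2, 10))
        coeffs = rng.normal(size=(30, 2))
        X = pd.DataFrame(coeffs @ basis)
        reduced, cum = gc.pca_reduce(X, gc.ClusteringConfig(variance_target=0.999))
        assert reduced.shape[1] == 2
        assert cum[1] >= 1 - 1e-10

    def test_target_one_keeps_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        reduced, _ = gc.pca_reduce(X, gc.ClusteringConfig(variance_target=1.0, max_pcs=30))
        assert reduced.shape[1] == 6

    def test_rotation_invariant_variance(self, rng):
        X = rng.normal(size=(25, 8))
        Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        _, cum1 = gc.pca_reduce(pd.DataFrame(X))
        _, cum2 = gc.pca_reduce(pd.DataFrame(X @ Q))
        assert np.allclose(cum1, cum2, atol=1e-8)


class TestPairwiseDistance:
    def test_affine_rows_pearson_zero(self):
        x = np.arange(10.0)
        X = np.vstack([x, 3 * x + 7])
        d = gc.pairwise_distance(X, "pearson")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("metric", gc.METRICS)
    def test_identical_rows_distance_zero(self, metric):
        X = np.vstack([np.arange(8.0), np.arange(8.0)])
        d = gc.pairwise_distance(X, metric)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        d1 = gc.pairwise_distance(np.vstack([x, y]), "spearman")[0, 1]
        d2 = gc.pairwise_distance(np.vstack([np.exp(x), y]), "spearman")[0, 1]
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestKmeans:
    def _blobs(self, rng, k=3, n=20, sep=20.0, dim=4):
        centers = rng.normal(size=(k, dim)) * sep
        X, labels = [], []
        for c in range(k):
            X.append(centers[c] + rng.normal(size=(n, dim)))
            labels += [c] * n
        return np.vstack(X), np.array(labels)

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan"])
    def test_separated_blobs_recovered(self, rng, metric):
        X, truth = self._blobs(rng)
        labels = gc.kmeans_cluster(X, 3, metric=metric, restarts=5, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_one(self, rng):
        X = rng.normal(size=(10, 3))
        labels = gc.kmeans_cluster(X, 1, "euclidean")
        assert (labels == 0).all()

    def test_same_seed_identical(self, rng):
        X = rng.normal(size=(40, 5))
        a = gc.kmeans_cluster(X, 4, "pearson", restarts=3, seed=7)
        b = gc.kmeans_cluster(X, 4, "pearson", restarts=3, seed=7)
        assert (a == b).all()

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            gc.kmeans_cluster(rng.normal(size=(3, 2)), 5, "euclidean")

    def test_pearson_lloyd_equivalence(self, rng):
        """Euclidean assignment on standardized features equals direct
        1 - r assignment to the standardized centroids."""
        for _ in range(10):
            X = rng.normal(size=(30, 8))
            F = gc.metric_features(X, "pearson")
            centroids = gc._standardize_rows(rng.normal(size=(4, 8)))
            eucl = gc._assign(F, centroids, "pearson")
            direct = np.array(
                [
                    np.argmin([1 - np.corrcoef(x, c)[0, 1] for c in centroids])
                    for x in X
                ]
            )
            assert (eucl == direct).all()


class TestSilhouetteSelect:
    def test_planted_waves_select_pearson_k8(self):
        X, truth = make_wave_matrix(seed=0)
        cfg = gc.ClusteringConfig(k_range=tuple(range(2, 13)), restarts=8, seed=0)
        waves = gc.silhouette_select(X, cfg)
        assert waves.metric == "pearson"
        assert abs(waves.k - 8) <= 1
        assert adjusted_rand_score(truth, waves.labels.to_numpy()) >= 0.8

    def test_single_blob_prefers_smallest_k(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)) * 0.01 + 5)
        cfg = gc.ClusteringConfig(metrics=("euclidean",), k_range=(2, 3, 4, 5), seed=1)
        waves = gc.silhouette_select(X, cfg)
        grid = waves.silhouette_grid.loc["euclidean"]
        assert waves.k == int(grid.idxmax())

    def test_true_split_beats_random_split(self, rng):
        from sklearn.metrics import silhouette_score

        X = np.vstack([rng.normal(size=(15, 4)), rng.normal(size=(15, 4)) + 12])
        D = gc.pairwise_distance(X, "euclidean")
        good = np.repeat([0, 1], 15)
        bad = np.tile([0, 1], 15)
        assert silhouette_score(D, good, metric="precomputed") > silhouette_score(
            D, bad, metric="precomputed"
        )

    def test_silhouette_widths_in_range(self):
        X, _ = make_wave_matrix(n_clusters=3, tfs_per_cluster=8, seed=2)
        cfg = gc.ClusteringConfig(metrics=("pearson", "euclidean"), k_range=(2, 3, 4), seed=0)
        waves = gc.silhouette_select(X, cfg)
        vals = waves.silhouette_grid.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert ((vals >= -1) & (vals <= 1)).all()


class TestHierarchical:
    def test_duplicate_columns_merge_first(self, rng):
        base = rng.normal(size=(20,))
        m = pd.DataFrame(
            {"a": base, "b": rng.normal(size=20), "c": base, "d": rng.normal(size=20)}
        )
        Z, order = gc.hierarchical_cluster_samples(m)
        # first merge joins the two identical columns at height ~0
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        ia, ic = order.index("a"), order.index("c")
        assert abs(ia - ic) == 1

    def test_leaf_order_stable(self, rng):
        m = pd.DataFrame(rng.normal(size=(15, 6)), columns=list("fedcba"))
        _, order1 = gc.hierarchical_cluster_samples(m)
        _, order2 = gc.hierarchical_cluster_samples(m[list("abcdef")])
        assert order1 == order2

    def test_too_few_columns_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            gc.hierarchical_cluster_samples(pd.DataFrame(rng.normal(size=(5, 2))))
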