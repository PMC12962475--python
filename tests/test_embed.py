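"""Embedding, clustering, centroids and cross-embedding stability."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from songpath import (
    Clustering,
    Embedding2D,
    FeatureMatrix,
    N_PIXEL_FEATURES,
    centroids,
    cluster_syllables,
    embed_2d,
    stability_report,
    zscore_matrix,
)


def _point_mass_embedding():
    """Two point masses of 10 identical coordinate pairs each."""
    coords = np.vstack([np.tile([0.0, 0.0], (10, 1)), np.tile([5.0, 5.0], (10, 1))])
    return Embedding2D(coords=coords, method="pca", seed=0, n_neighbors=5, min_dist=0.1)


class TestEmbed2D:
    def test_deterministic_given_seed(self, three_type_matrix):
        m, _ = three_type_matrix
        e1 = embed_2d(m, seed=11)
        e2 = embed_2d(m, seed=11)
        assert np.array_equal(e1.coords, e2.coords)

    def test_separated_types_recovered(self, three_type_matrix):
        m, labels = three_type_matrix
        e = embed_2d(m, seed=42)
        assert silhouette_score(e.coords, labels) > 0.5

    def test_coordinates_appended_to_matrix(self, three_type_matrix):
        m, _ = three_type_matrix
        e = embed_2d(m, seed=3)
        assert np.array_equal(m.embedding, e.coords)

    def test_too_few_rows_rejected(self):
        m = FeatureMatrix(
            X=np.random.default_rng(0).normal(size=(9, N_PIXEL_FEATURES)),
            ids=[f"s{i}" for i in range(9)],
        )
        with pytest.raises(ValueError, match=">= 10"):
            embed_2d(zscore_matrix(m), method="pca")

    def test_unscored_matrix_rejected(self):
        m = FeatureMatrix(
            X=np.zeros((12, N_PIXEL_FEATURES)), ids=[f"s{i}" for i in range(12)]
        )
        with pytest.raises(ValueError, match="z-scored"):
            embed_2d(m, method="pca")

    def test_neighbor_autoshrink_warns(self):
        rng = np.random.default_rng(2)
        m = zscore_matrix(
            FeatureMatrix(
                X=rng.normal(size=(12, N_PIXEL_FEATURES)),
                ids=[f"s{i}" for i in range(12)],
            )
        )
        with pytest.warns(RuntimeWarning, match="shrinking"):
            e = embed_2d(m, n_neighbors=15, method="pca")
        assert e.n_neighbors == 11


class TestClustering:
    def test_kmeans_point_masses_split(self):
        c = cluster_syllables(_point_mass_embedding(), method="kmeans", k=2)
        assert c.k == 2
        assert sorted(np.bincount(c.labels)) == [10, 10]

    def test_density_same_input(self):
        c = cluster_syllables(
            _point_mass_embedding(), method="density", min_cluster_size=5
        )
        assert c.k == 2
        assert not np.any(c.labels == -1)

    def test_kmeans_and_density_agree_on_point_masses(self):
        e = _point_mass_embedding()
        a = cluster_syllables(e, method="kmeans", k=2)
        b = cluster_syllables(e, method="density", min_cluster_size=5)
        assert adjusted_rand_score(a.labels, b.labels) == 1.0

    def test_k_one_all_zero_labels(self):
        c = cluster_syllables(_point_mass_embedding(), method="kmeans", k=1)
        assert np.all(c.labels == 0)

    def test_k_exceeding_points_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_syllables(_point_mass_embedding(), method="kmeans", k=21)

    def test_relabeling_by_descending_size(self):
        coords = np.vstack(
            [np.tile([9.0, 9.0], (3, 1)), np.tile([0.0, 0.0], (12, 1))]
        )
        e = Embedding2D(coords=coords, method="pca", seed=0, n_neighbors=5, min_dist=0.1)
        c = cluster_syllables(e, method="kmeans", k=2)
        assert np.all(c.labels[3:] == 0)  # larger cluster gets label 0
        assert np.all(c.labels[:3] == 1)

    def test_row_order_invariance(self):
        e = _point_mass_embedding()
        perm = np.random.default_rng(0).permutation(20)
        e_perm = Embedding2D(
            coords=e.coords[perm], method="pca", seed=0, n_neighbors=5, min_dist=0.1
        )
        a = cluster_syllables(e, method="kmeans", k=2)
        b = cluster_syllables(e_perm, method="kmeans", k=2)
        # same partition after undoing the permutation
        assert adjusted_rand_score(a.labels, b.labels[np.argsort(perm)]) == 1.0


class TestCentroids:
    def _embedding(self, pts):
        return Embedding2D(
            coords=np.asarray(pts, float), method="pca", seed=0,
            n_neighbors=5, min_dist=0.1,
        )

    def test_arithmetic_mean(self):
        e = self._embedding([[0, 0], [2, 2]])
        c = Clustering(labels=np.array([0, 0]), k=1, method="kmeans")
        assert np.allclose(centroids(e, c).centroids[0], [1, 1])

    def test_singleton_cluster_is_the_point(self):
        e = self._embedding([[3.5, -1.2]])
        c = Clustering(labels=np.array([0]), k=1, method="kmeans")
        for agg in ("arithmetic", "geometric"):
            assert np.allclose(centroids(e, c, agg).centroids[0], [3.5, -1.2])

    def test_geometric_mean_positive_coords(self):
        e = self._embedding([[1, 1], [4, 4]])
        c = Clustering(labels=np.array([0, 0]), k=1, method="kmeans")
        assert np.allclose(centroids(e, c, "geometric").centroids[0], [2, 2])

    def test_geometric_nonpositive_without_shift_rejected(self):
        e = self._embedding([[-1, 2], [3, 2]])
        c = Clustering(labels=np.array([0, 0]), k=1, method="kmeans")
        with pytest.raises(ValueError, match="shift"):
            centroids(e, c, "geometric", shift=False)
        centroids(e, c, "geometric", shift=True)  # shift convention works

    def test_noise_points_excluded(self):
        e = self._embedding([[0, 0], [2, 2], [100, 100]])
        c = Clustering(labels=np.array([0, 0, -1]), k=1, method="density")
        cs = centroids(e, c)
        assert np.allclose(cs.centroids[0], [1, 1])
        assert cs.cluster_sizes.sum() == 2

    def test_centroid_inside_bounding_box(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(30, 2)) * 5
        e = self._embedding(pts)
        c = Clustering(labels=rng.integers(0, 3, 30), k=3, method="kmeans")
        cs = centroids(e, c)
        for j in range(3):
            cluster_pts = pts[c.labels == j]
            assert np.all(cs.centroids[j] >= cluster_pts.min(axis=0) - 1e-12)
            assert np.all(cs.centroids[j] <= cluster_pts.max(axis=0) + 1e-12)


class TestStabilityReport:
    def _two_bird_matrix(self):
        """Bird A: one syllable type; bird B: five distinct types."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(6, N_PIXEL_FEATURES))
        rows, birds = [], []
        for _ in range(15):  # bird A: copies of one template
            rows.append(base[0] + 0.01 * rng.normal(size=N_PIXEL_FEATURES))
            birds.append("A")
        for t in range(1, 6):  # bird B: five templates
            for _ in range(3):
                rows.append(10 * base[t] + 0.01 * rng.normal(size=N_PIXEL_FEATURES))
                birds.append("B")
        m = zscore_matrix(
            FeatureMatrix(X=np.array(rows), ids=[f"s{i}" for i in range(30)])
        )
        return m, birds

    def test_diverse_bird_has_longer_path_under_every_seed(self):
        m, birds = self._two_bird_matrix()
        rep = stability_report(
            m, birds, seeds=[1, 2, 3], method="pca", cluster_method="kmeans", k=5
        )
        table = rep["path_lengths"]
        assert (table["B"] > table["A"]).all()

    def test_identical_seeds_give_perfect_correlation(self):
        m, birds = self._two_bird_matrix()
        rep = stability_report(m, birds, seeds=[7, 7], method="pca", k=5)
        assert rep["spearman"].iloc[0, 1] == 1.0

    def test_single_bird_correlation_undefined(self):
        m, birds = self._two_bird_matrix()
        rep = stability_report(
            m, ["A"] * len(birds), seeds=[1, 2], method="pca", k=5
        )
        assert np.isnan(rep["mean_offdiag_spearman"])
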