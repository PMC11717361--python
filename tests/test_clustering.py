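import numpy as np
import pytest

from retseq.clustering import (
    agglomerative_cluster,
    cluster_coherence,
    extract_sparse_features,
    fit_mixture_select_k,
    mea_feature_vector,
)


class TestSparseFeatures:
    def _population(self, rng, n=40):
        """Two cell groups differing only in one stimulus segment."""
        base = np.sin(np.linspace(0, 6 * np.pi, 120))
        chirp = np.tile(base, (n, 1)) + rng.normal(0, 0.05, (n, 120))
        chirp[: n // 2, 40:60] += 2.0
        bar = rng.normal(0, 0.05, (n, 30))
        bar[:, 10:15] += 1.0
        return chirp, bar

    def test_contrast_segment_concentrates_a_component(self, rng):
        chirp, bar = self._population(rng)
        feats = extract_sparse_features(chirp, bar, n_chirp=6, n_bar=3,
                                        alpha_grid=(0.5, 1.0, 2.0), seed=0)
        assert feats.X.shape == (40, 9)
        # the group contrast must be linearly separable from the features
        labels = np.array([0] * 20 + [1] * 20)
        mu0 = feats.X[labels == 0].mean(axis=0)
        mu1 = feats.X[labels == 1].mean(axis=0)
        assert np.max(np.abs(mu0 - mu1)) > 1.0

    def test_duplicate_cells_identical_rows(self, rng):
        chirp, bar = self._population(rng)
        chirp[1] = chirp[0]
        bar[1] = bar[0]
        feats = extract_sparse_features(chirp, bar, n_chirp=5, n_bar=3, seed=0)
        assert np.allclose(feats.X[0], feats.X[1], atol=1e-8)

    def test_standardization_contract(self, rng):
        chirp, bar = self._population(rng)
        feats = extract_sparse_features(chirp, bar, n_chirp=5, n_bar=3, seed=0)
        assert np.allclose(feats.X.mean(axis=0), 0.0, atol=1e-8)
        live = feats.X.std(axis=0) > 0
        assert np.allclose(feats.X.std(axis=0)[live], 1.0, atol=1e-8)


class TestMixtureSelection:
    def test_single_blob_selects_one(self, rng):
        X = rng.normal(size=(120, 4))
        model = fit_mixture_select_k(X, k_range=(1, 2, 3), n_folds=5,
                                     n_init=5, seed=0)
        assert model.chosen_k == 1

    def test_three_separated_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score
        centers = np.array([[0, 0], [10, 0], [0, 10]], float)
        labels_true = np.repeat([0, 1, 2], 100)
        X = centers[labels_true] + rng.normal(0, 1.0, size=(300, 2))
        model = fit_mixture_select_k(X, k_range=(1, 2, 3, 4), n_folds=5,
                                     n_init=10, seed=0)
        assert model.chosen_k == 3
        assert adjusted_rand_score(labels_true, model.labels) >= 0.99

    def test_bic_curve_deterministic_and_label_free(self, rng):
        """The selection curve depends only on data and seed, never on how
        the mixture components end up numbered."""
        X = rng.normal(size=(100, 3))
        m1 = fit_mixture_select_k(X, k_range=(1, 2), n_folds=4, n_init=3,
                                  seed=0)
        m2 = fit_mixture_select_k(X, k_range=(1, 2), n_folds=4, n_init=3,
                                  seed=0)
        assert m1.bic == m2.bic
        assert np.array_equal(m1.labels, m2.labels)
        # component numbering carries no information: the size multiset is
        # invariant under any relabeling
        perm = np.random.default_rng(0).permutation(m1.chosen_k)
        relabeled = perm[m1.labels]
        assert (sorted(np.bincount(relabeled, minlength=m1.chosen_k))
                == sorted(m1.sizes))

    def test_too_few_cells_errors(self, rng):
        with pytest.raises(ValueError):
            fit_mixture_select_k(rng.normal(size=(10, 2)),
                                 k_range=(1, 2, 3, 4))


class TestCoherence:
    def test_identical_traces_intra_one(self, rng):
        base = rng.random((2, 50))
        traces = np.vstack([base[0]] * 5 + [base[1]] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        rep = cluster_coherence(traces + rng.normal(0, 1e-9, traces.shape),
                                labels)
        assert rep.intra[0] == pytest.approx(1.0, abs=1e-3)

    def test_orthogonal_families_coherent(self, rng):
        t = np.linspace(0, 2 * np.pi, 100)
        a = np.sin(t)[None, :] + rng.normal(0, 0.1, (8, 100))
        b = np.sin(5 * t)[None, :] + rng.normal(0, 0.1, (8, 100))
        traces = np.vstack([a, b])
        labels = np.array([0] * 8 + [1] * 8)
        rep = cluster_coherence(traces, labels)
        assert rep.coherent
        assert all(rep.inter[u] < 0.3 for u in rep.inter)

    def test_shuffled_labels_not_coherent(self, rng):
        t = np.linspace(0, 2 * np.pi, 100)
        a = np.sin(t)[None, :] + rng.normal(0, 0.1, (10, 100))
        b = np.sin(5 * t)[None, :] + rng.normal(0, 0.1, (10, 100))
        traces = np.vstack([a, b])
        labels = rng.permutation(np.array([0] * 10 + [1] * 10))
        rep = cluster_coherence(traces, labels)
        # with random labels intra ~ inter for at least one cluster
        gaps = [rep.intra[u] - rep.inter[u] for u in rep.intra]
        assert min(gaps) < 0.2

    def test_singleton_cluster_excluded(self, rng):
        traces = rng.random((5, 20))
        labels = np.array([0, 0, 1, 1, 2])
        with pytest.warns(UserWarning):
            rep = cluster_coherence(traces, labels)
        assert 2 in rep.excluded


class TestMEAFeatures:
    def test_psth_variance_contract(self, rng):
        psths = rng.random((30, 200))
        stas = rng.random((30, 40))
        areas = rng.random(30)
        feats = mea_feature_vector(psths, stas, areas)
        n_psth = sum(1 for s, _ in feats.provenance if s == "psth_pc")
        from sklearn.decomposition import PCA
        z = (psths - psths.mean(1, keepdims=True)) / psths.std(1, keepdims=True)
        ratios = PCA().fit(z).explained_variance_ratio_
        assert np.cumsum(ratios)[n_psth - 1] >= 0.80

    def test_area_normalized_to_unit_interval(self, rng):
        feats = mea_feature_vector(rng.random((10, 50)), rng.random((10, 20)),
                                   np.linspace(100, 900, 10))
        area_col = feats.X[:, -1]
        assert area_col.min() == 0.0 and area_col.max() == 1.0

    def test_identical_cells_identical_rows(self, rng):
        psths = rng.random((6, 50))
        psths[1] = psths[0]
        stas = rng.random((6, 20))
        stas[1] = stas[0]
        areas = rng.random(6)
        areas[1] = areas[0]
        feats = mea_feature_vector(psths, stas, areas)
        assert np.allclose(feats.X[0], feats.X[1], atol=1e-10)

    def test_too_few_cells_errors(self, rng):
        with pytest.raises(ValueError):
            mea_feature_vector(rng.random((2, 50)), rng.random((2, 20)),
                               rng.random(2))


class TestAgglomerative:
    def test_threshold_extremes(self, rng):
        X = rng.normal(size=(12, 4))
        assert len(np.unique(agglomerative_cluster(X, threshold=1e6))) == 1
        assert len(np.unique(agglomerative_cluster(X, threshold=1e-12))) == 12

    def test_two_blob_partition_matches_linkage_oracle(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (6, 3)),
                       rng.normal(0, 0.1, (6, 3)) + 5.0])
        labels = agglomerative_cluster(X, distance="euclidean",
                                       linkage="average", threshold=2.0)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        # brute-force check: any threshold inside the gap gives the same cut
        labels2 = agglomerative_cluster(X, distance="euclidean",
                                        linkage="average", threshold=4.0)
        assert np.array_equal(labels, labels2)

    def test_nonfinite_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            agglomerative_cluster(X)
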