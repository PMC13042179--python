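"""UMAP projection, consensus clustering, K selection, cluster metrics."""

import numpy as np
import pytest

from physiophen.phenotyping import (ConsensusClusterer, ConsensusResult,
                                    ProjectionConfig, assign_labels,
                                    cluster_metrics, consensus_cdf_auc, project,
                                    select_k)


def _blobs(rng, centers, n_per, std=1.0):
    return np.concatenate([c + std * rng.normal(size=(n_per, len(c)))
                           for c in centers])


class TestProjection:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 10))
        cfg = ProjectionConfig(seed=3)
        a = project(x, cfg)
        b = project(x, cfg)
        assert a.shape == (100, 2)
        assert np.array_equal(a, b)

    def test_separated_blobs_stay_separable(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(1)
        x = _blobs(rng, [np.zeros(10), np.full(10, 12.0)], 150)
        y = np.repeat([0, 1], 150)
        pts = project(x, ProjectionConfig(seed=0))
        knn = KNeighborsClassifier(n_neighbors=1)
        err = 1.0 - knn.fit(pts, y).score(pts, y)
        assert err < 0.05

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            project(np.zeros((10, 3)), ProjectionConfig(n_neighbors=30))


class TestConsensus:
    def test_two_far_blobs_binary_consensus(self):
        rng = np.random.default_rng(0)
        x = _blobs(rng, [[0, 0], [100, 100]], 30, std=1.0)
        cc = ConsensusClusterer(k_range=(2,), n_iterations=50,
                                random_state=0)
        # single-K range is invalid for selection; use fit pieces instead
        cc = ConsensusClusterer(k_range=(2, 3), n_iterations=50, random_state=0)
        cc.fit(x)
        cons = cc.result_.consensus[2]
        same = np.repeat([0, 1], 30)
        within = cons[np.ix_(same == 0, same == 0)]
        between = cons[np.ix_(same == 0, same == 1)]
        assert np.nanmin(within) == 1.0
        assert np.nanmax(between) == 0.0

    def test_single_iteration_binary_entries(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 2))
        cc = ConsensusClusterer(k_range=(2, 3), n_iterations=1, random_state=0)
        cc.fit(x)
        vals = cc.result_.consensus[2]
        finite = vals[np.isfinite(vals)]
        assert set(np.unique(finite)) <= {0.0, 1.0}

    def test_duplicated_points_always_coclustered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 2))
        x[1] = x[0]  # exact duplicate pair
        cc = ConsensusClusterer(k_range=(2, 3, 4), n_iterations=60,
                                random_state=0).fit(x)
        for k in (2, 3, 4):
            v = cc.result_.consensus[k][0, 1]
            if np.isfinite(v):
                assert v == 1.0

    def test_matrices_symmetric_unit_interval(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 2))
        cc = ConsensusClusterer(random_state=0).fit(x)
        for k, cons in cc.result_.consensus.items():
            finite = np.isfinite(cons)
            assert np.array_equal(finite, finite.T)
            np.testing.assert_allclose(cons[finite],
                                       cons.T[finite], atol=1e-12)
            assert (cons[finite] >= 0).all() and (cons[finite] <= 1).all()

    def test_cdf_monotone_zero_to_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 2))
        cc = ConsensusClusterer(random_state=0).fit(x)
        for cdf in cc.result_.cdfs.values():
            assert (np.diff(cdf) >= -1e-12).all()
            assert cdf[-1] == pytest.approx(1.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ConsensusClusterer().fit(np.zeros((10, 2)))


class TestSelectK:
    def test_four_planted_blobs_majority(self):
        """K* = 4 on clearly planted 4-blob data, 20-seed majority."""
        centers = [[0, 0], [10, 0], [0, 10], [10, 10]]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = _blobs(rng, centers, 100)
            cc = ConsensusClusterer(random_state=seed).fit(x)
            hits += cc.k_selected_ == 4
        assert hits > 10

    def test_single_blob_flagged_unstable(self):
        rng = np.random.default_rng(0)
        cc = ConsensusClusterer(random_state=0).fit(rng.normal(size=(400, 2)))
        assert cc.k_selected_ == min(cc.k_range)
        assert not cc.result_.stable

    def test_ideal_binary_cdf_two_step(self):
        """An ideal block-diagonal consensus matrix yields a CDF that is a
        two-step function: flat after the between-cluster mass at 0, then
        jumping to 1 at consensus = 1."""
        n = 40
        labels = np.repeat([0, 1], n // 2)
        cons = (labels[:, None] == labels[None, :]).astype(float)
        grid = np.linspace(0, 1, 101)
        cdf, auc = consensus_cdf_auc(cons, grid)
        between = (n // 2) ** 2 / (n * (n - 1) / 2)
        assert cdf[0] == pytest.approx(between)
        assert np.allclose(cdf[:-1], between)  # flat until the last grid point
        assert cdf[-1] == 1.0

    def test_short_k_range_rejected(self):
        res = ConsensusResult(k_range=(2,), aucs={2: 0.5})
        with pytest.raises(ValueError):
            select_k(res)

    def test_separation_ladder_monotone(self):
        """Increasing blob separation never degrades K-correctness or
        silhouette."""
        sil = []
        correct = []
        for sep in (4.0, 8.0, 16.0):
            rng = np.random.default_rng(7)
            centers = [[0, 0], [sep, 0], [0, sep], [sep, sep]]
            x = _blobs(rng, centers, 80)
            cc = ConsensusClusterer(random_state=0).fit(x)
            correct.append(cc.k_selected_ == 4)
            sil.append(cluster_metrics(x, cc.labels_)["silhouette"]
                       if len(set(cc.labels_)) > 1 else -1.0)
        assert correct == sorted(correct)
        assert sil == sorted(sil)


class TestAssignLabels:
    def test_binary_blocks_recovered_with_full_confidence(self):
        labels_true = np.repeat([0, 1, 2], 10)
        cons = (labels_true[:, None] == labels_true[None, :]).astype(float)
        labels, conf = assign_labels(cons, 3)
        # same partition up to label names
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels_true, labels) == 1.0
        assert np.allclose(conf, 1.0)

    def test_confidence_in_unit_interval(self):
        rng = np.random.default_rng(0)
        cons = np.clip(rng.random((30, 30)), 0, 1)
        cons = (cons + cons.T) / 2
        labels, conf = assign_labels(cons, 3)
        assert ((conf >= 0) & (conf <= 1)).all()
        assert set(labels) == set(range(1, len(set(labels)) + 1))


class TestClusterMetrics:
    def test_hand_computed_four_point_silhouette(self):
        """(0,0),(0,1),(10,0),(10,1) in two pairs: brute-force silhouette."""
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        # brute force from the definition
        svals = []
        for i in range(4):
            own = [j for j in range(4) if labels[j] == labels[i] and j != i]
            other = [j for j in range(4) if labels[j] != labels[i]]
            a = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in own])
            b = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in other])
            svals.append((b - a) / max(a, b))
        expected = float(np.mean(svals))
        got = cluster_metrics(pts, labels)["silhouette"]
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.9005, abs=1e-3)

    def test_far_blobs_high_silhouette(self):
        rng = np.random.default_rng(0)
        x = _blobs(rng, [[0, 0], [100, 0]], 100, std=1.0)
        labels = np.repeat([0, 1], 100)
        assert cluster_metrics(x, labels)["silhouette"] > 0.95

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(500, 2))
        labels = rng.integers(0, 2, size=500)
        s = cluster_metrics(x, labels)["silhouette"]
        assert abs(s) < 0.05

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_metrics(np.zeros((10, 2)), np.zeros(10))
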