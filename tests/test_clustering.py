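"""Capping, standardisation, K-means, consensus/PAC, DB index, profiles."""

import numpy as np
import pandas as pd
import pytest

from apoptomap.clustering import (
    cap_extremes,
    consensus_cluster,
    davies_bouldin_index,
    down_select_markers,
    kmeans_fit,
    patient_cluster_profile,
    standardize,
)


class TestCapExtremes:
    def test_hand_quantiles_1_to_100(self):
        x = np.arange(1.0, 101.0).reshape(-1, 1)
        out = cap_extremes(x, 0.01)
        # linear-interpolation quantiles of 1..100: q(0.01)=1.99, q(0.99)=99.01
        assert out.min() == pytest.approx(1.99)
        assert out.max() == pytest.approx(99.01)

    def test_median_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, (500, 3))
        out = cap_extremes(x)
        np.testing.assert_allclose(np.median(out, axis=0), np.median(x, axis=0))

    @pytest.mark.parametrize("bad", [0.0, 0.5, -0.1])
    def test_invalid_tail_fraction(self, bad):
        with pytest.raises(ValueError):
            cap_extremes(np.ones((5, 2)), bad)

    def test_constant_column_unchanged(self):
        x = np.column_stack([np.ones(50), np.arange(50.0)])
        out = cap_extremes(x)
        np.testing.assert_allclose(out[:, 0], 1.0)

    def test_commutes_with_row_permutation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 4))
        perm = rng.permutation(200)
        a = standardize(cap_extremes(x))[0][perm]
        b = standardize(cap_extremes(x[perm]))[0]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestStandardize:
    def test_two_point_column(self):
        z, mu, sd = standardize(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.0, 1.0])
        assert mu[0] == 1.0 and sd[0] == 1.0

    def test_idempotent_and_invertible(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3, 7, (100, 5))
        z, mu, sd = standardize(x)
        z2, mu2, sd2 = standardize(z)
        np.testing.assert_allclose(z2, z, atol=1e-9)
        np.testing.assert_allclose(z * sd + mu, x, atol=1e-9)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1, atol=1e-9)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestKmeans:
    def test_separable_point_masses(self):
        x = np.concatenate([np.full(50, -10.0), np.full(50, 10.0)]).reshape(-1, 1)
        model = kmeans_fit(x, k=2, seed=0)
        assert sorted(model.centroids.ravel()) == pytest.approx([-10.0, 10.0])
        assert model.inertia == pytest.approx(0.0)
        assert set(model.labels) == {1, 2}

    def test_distortion_decreases_in_k(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(300, 4))
        inertias = [kmeans_fit(x, k, seed=0).inertia for k in range(2, 8)]
        assert all(a >= b for a, b in zip(inertias, inertias[1:]))

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 3))
        a = kmeans_fit(x, 4, seed=9).labels
        b = kmeans_fit(x, 4, seed=9).labels
        np.testing.assert_array_equal(a, b)


class TestConsensus:
    def test_two_separated_blobs_perfectly_stable(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(-10, 0.1, (60, 2)), rng.normal(10, 0.1, (60, 2))])
        res = consensus_cluster(x, k_range=[2, 3, 4], n_subsamples=20, seed=0)
        assert res.pac[2] == pytest.approx(0.0)
        assert res.selected_k == 2
        cons = res.consensus[2]
        off_diag = cons[np.triu_indices_from(cons, k=1)]
        assert np.all((off_diag > 0.99) | (off_diag < 0.01))

    def test_consensus_matrix_invariants(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(80, 3))
        res = consensus_cluster(x, k_range=[2, 3], n_subsamples=10, seed=1)
        for k, cons in res.consensus.items():
            assert np.allclose(cons, cons.T)
            assert np.allclose(np.diag(cons), 1.0)
            assert cons.min() >= 0 and cons.max() <= 1
            assert 0.0 <= res.pac[k] <= 1.0

    def test_subsample_too_small_rejected(self):
        with pytest.raises(ValueError, match="subsample"):
            consensus_cluster(np.random.default_rng(0).normal(size=(20, 2)),
                              k_range=[18], n_subsamples=5, subsample_frac=0.5)


class TestDaviesBouldin:
    def test_zero_scatter_clusters(self):
        x = np.array([[0.0], [0.0], [20.0], [20.0]])
        labels = [1, 1, 2, 2]
        assert davies_bouldin_index(x, labels) == pytest.approx(0.0)

    def test_hand_example(self):
        # clusters {0,2} and {10,12}: S1=S2=1, M=10 -> DB = 0.2
        x = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert davies_bouldin_index(x, [1, 1, 2, 2]) == pytest.approx(0.2)

    def test_matches_sklearn(self):
        from sklearn.metrics import davies_bouldin_score
        rng = np.random.default_rng(7)
        x = rng.normal(size=(120, 4))
        labels = kmeans_fit(x, 3, seed=0).labels
        assert davies_bouldin_index(x, labels) == pytest.approx(
            davies_bouldin_score(x, labels), rel=1e-9)

    def test_decreases_with_separation(self):
        rng = np.random.default_rng(8)
        vals = []
        for sep in (2.0, 5.0, 10.0):
            x = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(sep, 1, (100, 2))])
            labels = np.repeat([1, 2], 100)
            vals.append(davies_bouldin_index(x, labels))
        assert vals[0] > vals[1] > vals[2]


class TestDownSelect:
    def test_drops_planted_noise_marker(self):
        rng = np.random.default_rng(9)
        centers = rng.normal(0, 3, (4, 5))
        labels = rng.integers(0, 4, 600)
        informative = centers[labels] + rng.normal(0, 0.5, (600, 5))
        noise = rng.normal(0, 1, (600, 1))
        x = np.hstack([informative, noise])
        names = ["m1", "m2", "m3", "m4", "m5", "junk"]
        kept = down_select_markers(x, names, k=4, seed=0)
        assert "junk" not in kept
        assert len(kept) >= 3  # weakly-contributing markers may also go

    def test_exchangeable_informative_panel_retained(self):
        # regular tetrahedron: markers are exchangeable, removal of any one
        # worsens separation-to-scatter, so the full panel survives
        rng = np.random.default_rng(10)
        centers = 4.0 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        labels = rng.integers(0, 4, 400)
        x = centers[labels] + rng.normal(0, 0.5, (400, 3))
        kept = down_select_markers(x, ["a", "b", "c"], k=4, seed=0)
        assert kept == ("a", "b", "c")

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(200, 4))
        a = down_select_markers(x, list("abcd"), k=3, seed=5)
        b = down_select_markers(x, list("abcd"), k=3, seed=5)
        assert a == b


class TestPatientProfile:
    def test_single_patient_fractions(self):
        prof = patient_cluster_profile([1, 1, 2, 3], ["p1"] * 4, cluster_ids=[1, 2, 3, 4])
        row = prof.loc["p1"]
        assert row["cluster_1"] == 0.5
        assert row["cluster_2"] == 0.25
        assert row["cluster_3"] == 0.25
        assert row["cluster_4"] == 0.0
        assert row["dominant_cluster"] == 1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(1, 7, 500)
        pids = rng.choice(["p1", "p2", "p3"], 500)
        prof = patient_cluster_profile(labels, pids)
        sums = prof[[c for c in prof.columns if c.startswith("cluster_")]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_pooled_across_cores_not_averaged(self):
        # core A: 3 cells of cluster 1; core B: 1 cell of cluster 2.
        # pooled: (0.75, 0.25); per-core averaging would give (0.5, 0.5)
        prof = patient_cluster_profile([1, 1, 1, 2], ["p1"] * 4, cluster_ids=[1, 2])
        assert prof.loc["p1", "cluster_1"] == 0.75
        assert prof.loc["p1", "cluster_2"] == 0.25
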