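"""Neighbor distributions, KL loss, training and map-quality statistics."""

import math

import numpy as np
import pytest

from macroscape import fixtures as fx
from macroscape import tsne
from tests.conftest import TRAIN_CONFIG


class TestConditionalP:
    def test_equidistant_triplet_is_uniform(self):
        # Three mutually equidistant points: both neighbors get 1/2.
        X = np.eye(3)
        nd = tsne.conditional_p(X, perplexity=2.0)
        off = ~np.eye(3, dtype=bool)
        assert nd.conditional[off] == pytest.approx(0.5)

    def test_symmetrized_p_is_normalized_and_symmetric(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(30, 64)).astype(float)
        nd = tsne.conditional_p(X, perplexity=8.0)
        assert nd.p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(nd.p, nd.p.T)
        assert np.all(np.diag(nd.p) == 0)
        assert np.all(nd.p >= 0)

    @pytest.mark.parametrize("metric", ["euclidean", "jaccard"])
    def test_perplexity_calibration_on_random_fingerprints(self, metric):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(50, 128)).astype(float)
        perplexity = 15.0
        nd = tsne.conditional_p(X, perplexity, metric=metric)
        for i in range(50):
            row = nd.conditional[i][np.arange(50) != i]
            nz = row > 0
            h_bits = -np.sum(row[nz] * np.log2(row[nz]))
            assert 2**h_bits == pytest.approx(perplexity, abs=1e-3)

    def test_perplexity_must_be_below_n(self):
        with pytest.raises(ValueError):
            tsne.conditional_p(np.eye(5), perplexity=5.0)


class TestMapQ:
    def test_two_points_split_evenly_regardless_of_distance(self):
        for scale in [0.1, 100.0]:
            q = tsne.map_q(np.array([[0.0, 0.0], [scale, 0.0]]))
            assert q[0, 1] == pytest.approx(0.5)
            assert q[1, 0] == pytest.approx(0.5)

    def test_coincident_points_have_largest_affinity(self):
        Y = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, -3.0]])
        q = tsne.map_q(Y)
        assert q[0, 1] == q.max()

    def test_square_symmetry(self):
        Y = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        q = tsne.map_q(Y)
        sides = [q[0, 1], q[1, 2], q[2, 3], q[3, 0]]
        assert sides == pytest.approx([sides[0]] * 4)


class TestKlLoss:
    def test_zero_iff_equal(self):
        q = tsne.map_q(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]]))
        assert tsne.kl_loss(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_distributions(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random((5, 5))
            np.fill_diagonal(p, 0)
            p /= p.sum()
            q = rng.random((5, 5))
            np.fill_diagonal(q, 0)
            q /= q.sum()
            assert tsne.kl_loss(p, q) >= -1e-12

    def test_matches_bruteforce_sum(self):
        # Oracle: direct elementwise loop evaluation of sum p log(p/q).
        p = np.array([[0.0, 0.2, 0.1], [0.2, 0.0, 0.15], [0.1, 0.15, 0.0]])
        q = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.25], [0.2, 0.25, 0.0]])
        expected = 0.0
        for i in range(3):
            for j in range(3):
                if i != j and p[i, j] > 0:
                    expected += p[i, j] * math.log(p[i, j] / q[i, j])
        assert tsne.kl_loss(p, q) == pytest.approx(expected, rel=1e-12)

    def test_zero_q_under_positive_p_rejected(self):
        p = np.array([[0.0, 1.0], [0.0, 0.0]])
        q = np.zeros((2, 2))
        with pytest.raises(ValueError):
            tsne.kl_loss(p, q)


def pairwise_map_distances(Y):
    d = Y[:, None, :] - Y[None, :, :]
    return np.sqrt((d**2).sum(-1))


class TestTraining:
    def test_loss_decreases_on_synthetic_clusters(self, trained_model):
        trace = trained_model.training_loss_trace
        assert all(np.isfinite(trace))
        assert trace[-1] < trace[0]

    def test_clusters_separate_in_map(self, trained_model, split_cluster_data):
        X_train, labels, _, _ = split_cluster_data
        Y = tsne.transform(trained_model, X_train)
        D = pairwise_map_distances(Y)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), 1)
        intra = D[iu][same[iu]].mean()
        inter = D[iu][~same[iu]].mean()
        assert intra < inter

    def test_same_seed_reproduces_weights(self, trained_model, split_cluster_data):
        X_train, _, _, _ = split_cluster_data
        again = tsne.train(X_train, TRAIN_CONFIG)
        for (W1, b1), (W2, b2) in zip(trained_model.weights, again.weights):
            assert np.array_equal(W1, W2)
            assert np.array_equal(b1, b2)

    def test_projection_is_pure_function_of_weights(self, trained_model, split_cluster_data):
        X_train, _, _, _ = split_cluster_data
        a = tsne.transform(trained_model, X_train)
        b = tsne.transform(trained_model, X_train)
        assert np.array_equal(a, b)
        dup = tsne.transform(trained_model, np.vstack([X_train[:1], X_train[:1]]))
        assert np.array_equal(dup[0], dup[1])

    def test_out_of_sample_points_land_near_their_cluster(
        self, trained_model, split_cluster_data
    ):
        X_train, train_labels, X_test, test_labels = split_cluster_data
        Y_train = tsne.transform(trained_model, X_train)
        Y_test = tsne.transform(trained_model, X_test)
        centroids = np.array(
            [Y_train[train_labels == c].mean(axis=0) for c in range(3)]
        )
        for y, lab in zip(Y_test, test_labels):
            dists = np.linalg.norm(centroids - y, axis=1)
            assert np.argmin(dists) == lab

    def test_fingerprint_length_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError):
            tsne.transform(trained_model, np.zeros((4, 77)))

    def test_project_attaches_metadata(self, trained_model, split_cluster_data):
        X_train, _, _, _ = split_cluster_data
        points = tsne.project(
            trained_model,
            X_train[:2],
            inchi_keys=["K1", "K2"],
            families=["SLC5", "SLC6"],
            aggregated_pchembl=[6.5, None],
        )
        assert points[0].inchi_key == "K1"
        assert points[1].aggregated_pchembl is None
        assert np.isfinite([points[0].x, points[0].y]).all()

    def test_model_roundtrips_through_serialization(self, trained_model, tmp_path, split_cluster_data):
        X_train, _, _, _ = split_cluster_data
        tsne.save_model(trained_model, tmp_path / "model")
        loaded = tsne.load_model(tmp_path / "model")
        assert np.array_equal(
            tsne.transform(loaded, X_train), tsne.transform(trained_model, X_train)
        )
        assert loaded.config == trained_model.config


def bruteforce_trustworthiness(X, Y, k):
    """Rank-based trustworthiness computed with explicit loops."""
    n = len(X)
    dx = pairwise_map_distances(np.asarray(X, dtype=float))
    dy = pairwise_map_distances(np.asarray(Y, dtype=float))
    total = 0.0
    for i in range(n):
        order_x = np.argsort(dx[i], kind="stable")
        # ranks among the other points, 1-based
        rank_in_x = {}
        r = 0
        for j in order_x:
            if j == i:
                continue
            r += 1
            rank_in_x[j] = r
        nn_y = [j for j in np.argsort(dy[i], kind="stable") if j != i][:k]
        nn_x = set(j for j, r in rank_in_x.items() if r <= k)
        for j in nn_y:
            if j not in nn_x:
                total += rank_in_x[j] - k
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * total


class TestTrustworthiness:
    def test_identity_projection_scores_one(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(30, 2))
        assert tsne.trustworthiness(Y, Y, k=5) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 6))
        Y = rng.normal(size=(24, 2))
        assert tsne.trustworthiness(X, Y, k=5) == pytest.approx(
            bruteforce_trustworthiness(X, Y, 5), abs=1e-9
        )

    def test_trained_model_beats_random_projection(
        self, trained_model, split_cluster_data
    ):
        X_train, _, _, _ = split_cluster_data
        Y_model = tsne.transform(trained_model, X_train)
        rng = np.random.default_rng(8)
        Y_random = X_train @ rng.normal(size=(X_train.shape[1], 2))
        tw_model = tsne.trustworthiness(X_train, Y_model, k=12)
        tw_random = tsne.trustworthiness(X_train, Y_random, k=12)
        assert tw_model > tw_random

    def test_k_bound_enforced(self):
        with pytest.raises(ValueError):
            tsne.trustworthiness(np.zeros((10, 3)), np.zeros((10, 2)), k=5)


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(tsne.ConfigurationError):
            tsne.TsneConfig(perplexity=-1)
        with pytest.raises(tsne.ConfigurationError):
            tsne.TsneConfig(layer_sizes=(2048, 10, 3))
        with pytest.raises(tsne.ConfigurationError):
            tsne.TsneConfig(input_metric="cosine")

    def test_train_rejects_mismatched_input_layer(self):
        X = np.zeros((10, 32))
        with pytest.raises(tsne.ConfigurationError):
            tsne.train(X, tsne.TsneConfig(perplexity=3, layer_sizes=(16, 8, 2)))
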