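import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wordmanifold as wm
from wordmanifold.mlle import (
    alignment_matrix,
    embed,
    embedding_cost,
    fit,
    householder_weights,
    local_gram,
    median_eta,
    regularized_weights,
    split_rank,
)

from conftest import affine_residual


class TestLocalGram:
    def test_coincident_neighbors_all_zero(self):
        X = np.zeros((4, 3))
        G, sv = local_gram(X, 0, [1, 2, 3])
        assert np.all(G == 0) and np.all(sv == 0)

    def test_two_symmetric_neighbors_hand_svd(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        G, sv = local_gram(X, 0, [1, 2])
        np.testing.assert_allclose(G, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(sv, [np.sqrt(2), 0.0], atol=1e-12)

    def test_singvals_match_gram_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 6))
        G, sv = local_gram(X, 0, np.arange(1, 11))
        eig = np.sort(np.linalg.eigvalsh(G))[::-1]
        np.testing.assert_allclose(sv**2, np.clip(eig, 0, None), atol=1e-8)


class TestSplitRank:
    def test_clear_spectral_gap(self):
        r, s = split_rank(np.array([10.0, 10.0, 1e-12, 1e-12]), 4, 2, eta=1e-3)
        assert (r, s) == (2, 2)

    def test_clamped_when_k_is_d_plus_one(self):
        r, s = split_rank(np.array([5.0, 4.0, 3.0]), 3, 2, eta=1e3)
        assert s == 1 and r == 2

    def test_flat_spectrum_keeps_minimum_one(self):
        # no trailing block has small relative energy => clamp to s=1
        r, s = split_rank(np.full(6, 2.0), 6, 2, eta=1e-3)
        assert s == 1 and r == 5

    def test_zero_spectrum_takes_maximum(self):
        r, s = split_rank(np.zeros(6), 6, 2, eta=1e-3)
        assert s == 4 and r == 2

    def test_median_eta_matches_definition(self):
        evals = np.array([[4.0, 1.0, 0.5], [9.0, 1.0, 1.0]])
        # rho_i for d=1: (1+0.5)/4 and 2/9
        assert median_eta(evals, 1) == pytest.approx(
            np.median([1.5 / 4.0, 2.0 / 9.0])
        )


class TestRegularizedWeights:
    def test_degenerate_gram_gives_uniform(self):
        w = regularized_weights(np.zeros((5, 5)))
        np.testing.assert_allclose(w, 0.2)

    def test_midpoint_recovers_barycentric_identity(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        G, _ = local_gram(X, 0, [1, 2])
        w = regularized_weights(G, gamma_scale=1e-12)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)

    def test_beats_random_affine_weights(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 8))
        J = np.arange(1, 11)
        G, _ = local_gram(X, 0, J)
        w = regularized_weights(G, gamma_scale=1e-6)
        C = X[J] - X[0]
        best = np.linalg.norm(C.T @ w)
        for _ in range(1000):
            r = rng.standard_normal(10)
            r /= r.sum()
            assert np.linalg.norm(C.T @ r) >= best - 1e-9


class TestHouseholder:
    def test_single_uniform_direction_sums_to_one(self):
        k = 4
        V = np.full((k, 1), 1.0 / np.sqrt(k))
        w_reg = np.full(k, 0.25)
        hw = householder_weights(w_reg, V)
        assert hw.alpha == pytest.approx(np.sqrt(k))
        np.testing.assert_allclose(hw.W.sum(axis=0), 1.0, atol=1e-10)

    @given(st.integers(0, 500))
    def test_columns_sum_to_one_random_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 12))
        s = int(rng.integers(1, k))
        Q, _ = np.linalg.qr(rng.standard_normal((k, s)))
        G = rng.standard_normal((k, k))
        w_reg = regularized_weights(G @ G.T)
        hw = householder_weights(w_reg, Q)
        np.testing.assert_allclose(hw.W.sum(axis=0), 1.0, atol=1e-10)

    def test_householder_is_reflection_mapping_v(self):
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.standard_normal((7, 3)))
        hw = householder_weights(np.full(7, 1 / 7), Q)
        H = hw.H
        np.testing.assert_allclose(H @ H, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(H @ hw.v, hw.alpha * np.ones(3), atol=1e-10)

    def test_zero_v_degenerate_case_is_valid(self):
        # columns of V sum to zero => v = 0, alpha = 0, H = identity
        V = np.array([[1.0], [-1.0]]) / np.sqrt(2)
        hw = householder_weights(np.array([0.5, 0.5]), V)
        assert hw.alpha == 0.0
        np.testing.assert_allclose(hw.W.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(hw.H, np.eye(1))


class TestAlignment:
    def test_three_point_hand_assembly(self):
        from wordmanifold.mlle import LocalWeights

        def lw(J, w):
            w = np.asarray(w, float)[:, None]
            return LocalWeights(
                J=np.array(J), singvals=np.zeros(2), r=1, s=1,
                w_reg=w[:, 0], V=np.zeros((2, 1)), alpha=0.0,
                h=np.zeros(1), W=w,
            )

        weights = [lw([1, 2], [0.3, 0.7]), lw([0, 2], [0.5, 0.5]), lw([0, 1], [0.9, 0.1])]
        Phi = alignment_matrix(weights, 3)
        expected = np.zeros((3, 3))
        for i, (J, w) in enumerate(
            [([1, 2], [0.3, 0.7]), ([0, 2], [0.5, 0.5]), ([0, 1], [0.9, 0.1])]
        ):
            e = np.zeros(3)
            e[i] = 1.0
            e[J[0]] -= w[0]
            e[J[1]] -= w[1]
            expected += np.outer(e, e)
        np.testing.assert_allclose(Phi, expected, atol=1e-14)

    def test_quadratic_form_equals_termwise_cost(self, swiss_model):
        n, d = swiss_model.n, swiss_model.d
        Phi = alignment_matrix(swiss_model.weights, n)
        rng = np.random.default_rng(4)
        for _ in range(5):
            Y = rng.standard_normal((n, d))
            direct = embedding_cost(Y, swiss_model.weights)
            quad = float(np.trace(Y.T @ Phi @ Y))
            assert quad == pytest.approx(direct, rel=1e-9)

    def test_annihilates_constants_and_psd(self, swiss_model):
        Phi = alignment_matrix(swiss_model.weights, swiss_model.n)
        np.testing.assert_allclose(Phi @ np.ones(swiss_model.n), 0.0, atol=1e-10)
        rng = np.random.default_rng(5)
        for _ in range(50):
            y = rng.standard_normal(swiss_model.n)
            assert y @ Phi @ y >= -1e-10

    def test_missing_weights_rejected(self, swiss_model):
        with pytest.raises(ValueError):
            alignment_matrix(swiss_model.weights[:-1], swiss_model.n)


class TestEmbed:
    def test_columns_orthogonal_to_constant(self, swiss_model):
        ones = np.ones(swiss_model.n)
        np.testing.assert_allclose(ones @ swiss_model.Y_train, 0.0, atol=1e-8)

    def test_sign_convention_deterministic(self, swiss_model):
        for j in range(swiss_model.d):
            col = swiss_model.Y_train[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_dimension_bound(self):
        with pytest.raises(ValueError):
            embed(np.eye(4), 3)


class TestFit:
    def test_cost_identity_with_eigenvalues(self, swiss_model):
        # trace(Y^T Phi Y) over eigenvectors = sum of their eigenvalues
        direct = embedding_cost(swiss_model.Y_train, swiss_model.weights)
        assert direct == pytest.approx(float(swiss_model.eigvals[1:].sum()), abs=1e-8)

    def test_deterministic_given_seed(self, swiss_small):
        emb, _ = swiss_small
        m1 = fit(emb.vectors, k=8, d=2, seed=3)
        m2 = fit(emb.vectors, k=8, d=2, seed=3)
        assert np.array_equal(m1.Y_train, m2.Y_train)

    def test_planar_data_embeds_to_latent_affine(self, planar_data):
        X, lat = planar_data
        m = fit(X, k=10, d=2, gamma_scale=1e-10, seed=0)
        assert affine_residual(lat, m.Y_train) < 1e-6
        assert np.all(m.eigvals[1:] < 1e-8)

    def test_window_too_small_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="window"):
            fit(rng.standard_normal((8, 3)), k=8, d=2)

    def test_k_not_larger_than_d_warns_but_fits(self, caplog):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 4))
        with caplog.at_level(logging.WARNING, logger="wordmanifold"):
            m = fit(X, k=4, d=4, seed=0)
        assert "single weight vector" in caplog.text
        assert m.Y_train.shape == (40, 4)
        assert all(lw.s == 1 for lw in m.weights)

    def test_standard_operating_defaults(self):
        """k=500 on a 1001-word window starting at rank 0, d = input dim."""
        import inspect

        sig = inspect.signature(fit)
        assert sig.parameters["k"].default == 500
        from wordmanifold.cli import build_parser

        _, defaults = build_parser()
        assert defaults["fit"]["window_size"] == 1001
        assert defaults["fit"]["neighbors"] == 500
        assert defaults["fit"]["window_start"] == 0
        assert defaults["fit"]["dim"] is None  # d defaults to input dimension


class TestReferenceParity:
    def test_matches_sklearn_modified_lle_small(self, swiss_small):
        pytest.importorskip("sklearn")
        from scipy.spatial import procrustes
        from sklearn.manifold import locally_linear_embedding

        emb, _ = swiss_small
        X = emb.vectors
        mine = fit(X, k=10, d=2, metric="euclidean", seed=0)
        ref, _ = locally_linear_embedding(
            X, n_neighbors=10, n_components=2, method="modified",
            eigen_solver="dense",
        )
        _, _, disparity = procrustes(ref, mine.Y_train)
        assert disparity < 1e-3
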