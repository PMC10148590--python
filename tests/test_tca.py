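"""Transfer-component analysis: constructions, MMD identity, eigen oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudospace import (
    KernelSpec,
    build_centering_matrix_H,
    build_coefficient_matrix_L,
    compute_kernel,
    embed,
    fit_tca,
    mmd_trace,
)


class TestCoefficientMatrixL:
    def test_one_vs_one(self):
        np.testing.assert_allclose(
            build_coefficient_matrix_L(1, 1), [[1, -1], [-1, 1]], atol=1e-15
        )

    def test_two_vs_one(self):
        expected = [[0.25, 0.25, -0.5], [0.25, 0.25, -0.5], [-0.5, -0.5, 1.0]]
        np.testing.assert_allclose(
            build_coefficient_matrix_L(2, 1), expected, atol=1e-15
        )

    @given(n1=st.integers(1, 20), n2=st.integers(1, 20))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_outer_product_structure_and_zero_row_sums(self, n1, n2):
        L = build_coefficient_matrix_L(n1, n2)
        v = np.concatenate([np.full(n1, 1 / n1), np.full(n2, -1 / n2)])
        np.testing.assert_allclose(L, np.outer(v, v), atol=1e-12)
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(L, L.T, atol=1e-15)


class TestCenteringMatrixH:
    def test_small_cases(self):
        np.testing.assert_allclose(
            build_centering_matrix_H(2), [[0.5, -0.5], [-0.5, 0.5]], atol=1e-15
        )
        np.testing.assert_allclose(build_centering_matrix_H(1), [[0.0]])

    def test_idempotent(self):
        H = build_centering_matrix_H(5)
        np.testing.assert_allclose(H @ H, H, atol=1e-12)
        np.testing.assert_allclose(H.sum(axis=1), 0.0, atol=1e-12)


class TestComputeKernel:
    def test_linear_inner_products(self):
        K = compute_kernel(np.array([[0.0]]), np.array([[2.0]]),
                           KernelSpec("linear"))
        np.testing.assert_allclose(K, [[0, 0], [0, 4]], atol=1e-15)

    def test_rbf_unit_diagonal(self, rng):
        K = compute_kernel(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)),
                           KernelSpec("rbf", gamma=0.7))
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-15)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_rbf_small_gamma_limit_is_all_ones(self, rng):
        K = compute_kernel(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)),
                           KernelSpec("rbf", gamma=1e-12))
        np.testing.assert_allclose(K, 1.0, atol=1e-9)

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature"):
            compute_kernel(np.ones((2, 3)), np.ones((2, 4)), KernelSpec())


class TestMmdTrace:
    def test_hand_evaluated_one_dimensional_case(self):
        # linear-kernel MMD between {0} and {2} is ||0 - 2||^2 = 4
        K = np.array([[0.0, 0.0], [0.0, 4.0]])
        L = build_coefficient_matrix_L(1, 1)
        assert mmd_trace(K, L) == pytest.approx(4.0, abs=1e-12)

    def test_identical_samples_give_zero(self, rng):
        X = rng.normal(size=(6, 3))
        K = compute_kernel(X, X, KernelSpec("linear"))
        assert mmd_trace(K, build_coefficient_matrix_L(6, 6)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_linear_kernel_equals_squared_mean_difference(self, rng):
        # closed form of the linear-kernel MMD in 1-D
        xs = rng.normal(size=(5, 1))
        xt = rng.normal(size=(5, 1))
        K = compute_kernel(xs, xt, KernelSpec("linear"))
        L = build_coefficient_matrix_L(5, 5)
        expected = float((xs.mean() - xt.mean()) ** 2)
        assert mmd_trace(K, L) == pytest.approx(expected, abs=1e-10)

    def test_non_negative_for_psd_kernels(self, rng):
        for _ in range(20):
            xs = rng.normal(size=(4, 2))
            xt = rng.normal(size=(5, 2))
            for spec in (KernelSpec("linear"), KernelSpec("rbf", gamma=0.5)):
                K = compute_kernel(xs, xt, spec)
                L = build_coefficient_matrix_L(4, 5)
                assert mmd_trace(K, L) >= -1e-10


@pytest.fixture(scope="module")
def random_instance():
    rng = np.random.default_rng(42)
    Xs = rng.normal(size=(8, 5))
    Xt = rng.normal(size=(8, 5)) + 0.5
    model = fit_tca(Xs, Xt, KernelSpec("linear"), m=4, mu=1.0)
    return Xs, Xt, model


class TestFitTca:

    def test_pencil_residual_below_tolerance(self, random_instance):
        # the defining equation is its own oracle
        _, _, model = random_instance
        n = model.K.shape[0]
        H = build_centering_matrix_H(n)
        L = build_coefficient_matrix_L(*model.train_obs_split)
        KHK = model.K @ H @ model.K
        A = np.eye(n) + model.mu * (model.K @ L @ model.K)
        B = KHK + model.ridge * np.eye(n)
        M = np.linalg.solve(B, A)
        residual = M @ model.W - model.W @ np.diag(model.eigenvalues)
        assert np.abs(residual).max() < 1e-6

    def test_generalized_eigenvectors_are_B_orthogonal(self, random_instance):
        _, _, model = random_instance
        n = model.K.shape[0]
        H = build_centering_matrix_H(n)
        G = model.W.T @ (model.K @ H @ model.K) @ model.W
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6
        # constraint diag(W' K H K W) = 1 up to the ridge perturbation
        np.testing.assert_allclose(np.diag(G), 1.0, atol=1e-6)

    def test_eigenvalues_real_and_ascending(self, random_instance):
        _, _, model = random_instance
        assert np.isrealobj(model.eigenvalues)
        assert (np.diff(model.eigenvalues) >= -1e-12).all()

    def test_embedding_reduces_mean_shift_mmd(self):
        # pure mean-shift batch effect: the transform should shrink the
        # trace-normalized MMD, checked over 20 seeded instances
        reduced = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Xs = rng.normal(size=(15, 6))
            Xt = rng.normal(size=(15, 6)) + rng.normal(size=6)
            model = fit_tca(Xs, Xt, KernelSpec("linear"), m=3, mu=1.0)
            L = build_coefficient_matrix_L(15, 15)
            before = mmd_trace(model.K, L) / np.trace(model.K)
            KW = model.K @ model.W
            after = np.trace(KW.T @ L @ KW) / np.trace(KW @ KW.T)
            if after <= before:
                reduced += 1
        assert reduced == 20

    def test_embed_shapes_and_definition(self, random_instance):
        _, _, model = random_instance
        Xs_lat, Xt_lat = embed(model)
        assert Xs_lat.shape == (8, 4) and Xt_lat.shape == (8, 4)
        np.testing.assert_allclose(
            np.vstack([Xs_lat, Xt_lat]), model.K @ model.W, atol=1e-12
        )

    def test_single_observation_embedding_is_scalar_product(self):
        Xs = np.array([[1.0, 2.0]])
        Xt = np.array([[2.0, 1.0]])
        model = fit_tca(Xs, Xt, KernelSpec("linear"), m=1, mu=1.0)
        Xs_lat, Xt_lat = embed(model)
        assert Xs_lat.shape == (1, 1) and Xt_lat.shape == (1, 1)
        np.testing.assert_allclose(Xs_lat[0, 0], model.K[0] @ model.W[:, 0])

    def test_source_permutation_permutes_source_embedding(self):
        rng = np.random.default_rng(3)
        Xs = rng.normal(size=(7, 4))
        Xt = rng.normal(size=(6, 4))
        perm = rng.permutation(7)
        m1 = fit_tca(Xs, Xt, KernelSpec("linear"), m=3, mu=1.0)
        m2 = fit_tca(Xs[perm], Xt, KernelSpec("linear"), m=3, mu=1.0)
        a_s, a_t = embed(m1)
        b_s, b_t = embed(m2)
        # eigenvector signs are arbitrary: align columns by their largest
        # absolute entry before comparing
        for j in range(3):
            ref = a_t[:, j]
            if np.sign(ref[np.argmax(np.abs(ref))]) != np.sign(
                b_t[np.argmax(np.abs(ref)), j]
            ):
                b_s[:, j] *= -1
                b_t[:, j] *= -1
        np.testing.assert_allclose(b_s, a_s[perm], atol=1e-8)
        np.testing.assert_allclose(b_t, a_t, atol=1e-8)

    def test_m_too_large_rejected(self):
        with pytest.raises(ValueError, match="m="):
            fit_tca(np.ones((3, 2)), np.ones((3, 2)), m=6, mu=1.0)

    def test_target_subsampling_extends_by_nystrom(self):
        rng = np.random.default_rng(5)
        Xs = rng.normal(size=(10, 4))
        Xt = rng.normal(size=(30, 4))
        model = fit_tca(Xs, Xt, KernelSpec("linear"), m=3, mu=1.0,
                        seed=0, max_obs=25)
        Xs_lat, Xt_lat = embed(model)
        assert Xs_lat.shape == (10, 3)
        assert Xt_lat.shape == (30, 3)  # all target rows, not just anchors
        np.testing.assert_allclose(
            Xs_lat, (Xs @ model.X_fit.T) @ model.W, atol=1e-10
        )


class TestPersistence:
    def test_save_load_round_trip(self, random_instance, tmp_path):
        _, _, model = random_instance
        model.gene_fingerprint = "abc123"
        p = tmp_path / "tca.npz"
        model.save(p)
        back = model.__class__.load(p)
        np.testing.assert_array_equal(back.W, model.W)
        np.testing.assert_array_equal(back.K, model.K)
        assert back.spec.kind == model.spec.kind
        assert back.gene_fingerprint == "abc123"
        a1, b1 = embed(model)
        a2, b2 = embed(back)
        np.testing.assert_allclose(a2, a1, atol=1e-12)
        np.testing.assert_allclose(b2, b1, atol=1e-12)
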