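import numpy as np
import pytest

from grmec import solver as S
from grmec.evaluate import adjusted_rand_index
from grmec.io import ValidationError
from tests.conftest import make_random_instance


def classical_nmf_step(W, V, X, floor=S.DENOM_FLOOR):
    """Independent multiplicative-update NMF (the Lee-Seung rules)."""
    W = W * (X @ V.T) / np.maximum(W @ (V @ V.T), floor)
    V = V * (W.T @ X) / np.maximum((W.T @ W) @ V, floor)
    return W, V


class TestGraphPieces:
    def test_identical_rows_zero(self):
        M = np.vstack([np.ones(3), np.ones(3), np.arange(3.0)])
        D = S.pairwise_sq_dists(M)
        assert D[0, 1] == 0.0

    def test_unit_vectors(self):
        D = S.pairwise_sq_dists(np.eye(2))
        assert D[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(5, 3))
        D = S.pairwise_sq_dists(M)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(
                    float(np.sum((M[i] - M[j]) ** 2)), abs=1e-12
                )
        assert (D >= 0).all()
        np.testing.assert_array_equal(D, D.T)

    def test_laplacian_all_ones(self):
        D, L = S.laplacian(np.ones((3, 3)))
        np.testing.assert_allclose(np.diag(D), 3.0)
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-12)

    def test_laplacian_quadratic_form_identity(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(size=(6, 6))
        A = 0.5 * (A + A.T)
        _, L = S.laplacian(A)
        x = rng.normal(size=6)
        direct = 0.5 * sum(
            A[i, j] * (x[i] - x[j]) ** 2 for i in range(6) for j in range(6)
        )
        assert x @ L @ x == pytest.approx(direct, rel=1e-10)

    def test_laplacian_zero_and_asymmetric(self):
        _, L = S.laplacian(np.zeros((3, 3)))
        np.testing.assert_array_equal(L, 0.0)
        with pytest.raises(ValidationError):
            S.laplacian(np.array([[0.0, 1.0], [0.0, 0.0]]))


def _state_from(W, V, Sc, H, w, alpha):
    return S.ModelState(W=W, V=V, S=Sc, H=H, w=np.asarray(w), alpha=np.asarray(alpha))


class TestObjective:
    def test_zero_at_perfect_fit(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(size=(6, 3))
        V = {"a": rng.uniform(size=(3, 4))}
        X = W @ V["a"]
        Srv = [np.eye(6)]
        H = np.full((6, 2), 0.5)
        st = _state_from(W, V, np.eye(6), H, [1.0], [[1.0]])
        hp = S.HyperParams(C=2, k=3, lambda1=0.0, lambda2=0.0)
        assert S.objective(st, [X], Srv, hp) == pytest.approx(0.0, abs=1e-20)

    def test_lambda1_term_matches_bruteforce_graph_identity(self):
        rng = np.random.default_rng(1)
        n, k, C = 6, 3, 2
        W = rng.uniform(size=(n, k))
        H = rng.uniform(size=(n, C))
        H = H / H.sum(axis=1, keepdims=True)
        SH = H @ H.T
        _, LH = S.laplacian(SH)
        trace_form = np.trace(W.T @ LH @ W)
        brute = 0.5 * sum(
            np.sum((W[i] - W[j]) ** 2) * SH[i, j] for i in range(n) for j in range(n)
        )
        assert trace_form == pytest.approx(brute, rel=1e-10)

    def test_degenerate_limit_is_plain_reconstruction_error(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(size=(5, 2))
        V = {"a": rng.uniform(size=(2, 7))}
        X = rng.uniform(size=(5, 7))
        H = np.full((5, 2), 0.5)
        st = _state_from(W, V, np.zeros((5, 5)), H, [1.0], [[0.0]])
        hp = S.HyperParams(C=2, k=2, lambda1=0.0, lambda2=0.0)
        # with zero base weight the consensus term vanishes too
        assert S.objective(st, [X], [np.eye(5)], hp) == pytest.approx(
            np.linalg.norm(X - W @ V["a"], "fro") ** 2, rel=1e-12
        )


class TestUpdateW:
    def test_reduces_to_classical_nmf_without_graph(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(size=(8, 3))
        V = {"a": rng.uniform(size=(3, 6))}
        X = rng.uniform(size=(8, 6))
        ours = S.update_W(W, [X], V, np.array([1.0]), np.empty((8, 0)), 0.0)
        oracle = W * (X @ V["a"].T) / np.maximum(W @ (V["a"] @ V["a"].T), S.DENOM_FLOOR)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_fixed_point_at_exact_factorization(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(0.1, 1.0, size=(6, 2))
        V = {"a": rng.uniform(0.1, 1.0, size=(2, 5))}
        X = W @ V["a"]
        out = S.update_W(W, [X], V, np.array([1.0]), np.empty((6, 0)), 0.0)
        np.testing.assert_allclose(out, W, rtol=1e-12)

    def test_nonnegative_and_objective_nonincreasing(self):
        rng = np.random.default_rng(6)
        n, k = 10, 3
        W = rng.uniform(size=(n, k))
        V = {"a": rng.uniform(size=(k, 7)), "b": rng.uniform(size=(k, 5))}
        Xs = [rng.uniform(size=(n, 7)), rng.uniform(size=(n, 5))]
        H = rng.uniform(size=(n, 3))
        H = H / H.sum(1, keepdims=True)
        w = np.array([0.7, 0.3])
        hp = S.HyperParams(C=3, k=k, lambda1=0.1, lambda2=0.0)
        Srv = [np.eye(n)]
        before = S.objective(_state_from(W, V, np.eye(n), H, w, [[1.0]]), Xs, Srv, hp)
        Wn = S.update_W(W, Xs, V, w, H, hp.lambda1)
        after = S.objective(_state_from(Wn, V, np.eye(n), H, w, [[1.0]]), Xs, Srv, hp)
        assert (Wn >= 0).all()
        assert after <= before * (1 + 1e-8)


class TestUpdateV:
    def test_fixed_point_and_classical_equivalence(self):
        rng = np.random.default_rng(7)
        W = rng.uniform(0.1, 1.0, size=(6, 2))
        V = {"a": rng.uniform(0.1, 1.0, size=(2, 5))}
        X = W @ V["a"]
        out = S.update_V(W, [X], V)
        np.testing.assert_allclose(out["a"], V["a"], rtol=1e-12)

    def test_residual_nonincreasing(self):
        rng = np.random.default_rng(8)
        W = rng.uniform(size=(9, 3))
        V = {"a": rng.uniform(size=(3, 6))}
        X = rng.uniform(size=(9, 6))
        before = np.linalg.norm(X - W @ V["a"], "fro")
        out = S.update_V(W, [X], V)
        after = np.linalg.norm(X - W @ out["a"], "fro")
        assert after <= before * (1 + 1e-10)
        assert (out["a"] >= 0).all()


class TestUpdateS:
    def test_single_base_result_recovered_exactly(self):
        rng = np.random.default_rng(9)
        n = 8
        Sc = rng.uniform(0.1, 1.0, size=(n, n))
        Sc = 0.5 * (Sc + Sc.T)
        lab = rng.integers(0, 2, size=n)
        S11 = (lab[:, None] == lab[None, :]).astype(float)
        out = S.update_S(Sc, [S11], np.array([[0.37]]), np.empty((n, 0)), lambda2=0.0)
        np.testing.assert_array_equal(out, S11)

    def test_common_base_matrix_is_fixed_target(self):
        rng = np.random.default_rng(10)
        n = 6
        Sc = rng.uniform(0.2, 1.0, size=(n, n))
        Sc = 0.5 * (Sc + Sc.T)
        labels = np.array([0, 0, 1, 1, 2, 2])
        Sb = (labels[:, None] == labels[None, :]).astype(float)
        out = S.update_S(Sc, [Sb, Sb, Sb], np.array([0.2, 0.3, 0.5]), np.empty((n, 0)), 0.0)
        np.testing.assert_allclose(out, Sb, atol=1e-12)

    def test_consensus_term_nonincreasing(self):
        rng = np.random.default_rng(11)
        n = 10
        Sc = rng.uniform(size=(n, n))
        Sc = 0.5 * (Sc + Sc.T)
        Srv = []
        for _ in range(3):
            lab = rng.integers(0, 3, size=n)
            Srv.append((lab[:, None] == lab[None, :]).astype(float))
        alpha = rng.uniform(0.1, 1.0, size=3)
        H = rng.uniform(size=(n, 3))
        H = H / H.sum(1, keepdims=True)

        def term(Smat):
            val = sum(a * np.linalg.norm(Smat - Sb, "fro") ** 2 for a, Sb in zip(alpha, Srv))
            Dh = S.pairwise_sq_dists(H)
            return val + 0.01 / 2 * float((Dh * Smat).sum())

        out = S.update_S(Sc, Srv, alpha, H, lambda2=0.01)
        assert term(out) <= term(Sc) * (1 + 1e-8)
        np.testing.assert_allclose(out, out.T, atol=1e-15)


class TestUpdateH:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(12)
        n = 7
        H = rng.uniform(size=(n, 3))
        H = H / H.sum(1, keepdims=True)
        W = rng.uniform(size=(n, 2))
        Sc = rng.uniform(size=(n, n))
        Sc = 0.5 * (Sc + Sc.T)
        out = S.update_H(H, W, Sc, lambda1=0.1, lambda2=0.01)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out >= 0).all()

    def test_zero_lambda2_resets_rows_uniform_with_warning(self):
        rng = np.random.default_rng(13)
        H = rng.uniform(size=(5, 3))
        H = H / H.sum(1, keepdims=True)
        W = rng.uniform(size=(5, 2))
        Sc = np.eye(5)
        with pytest.warns(RuntimeWarning, match="uniform"):
            out = S.update_H(H, W, Sc, lambda1=0.1, lambda2=0.0)
        np.testing.assert_allclose(out, 1.0 / 3.0)

    def test_block_diagonal_affinity_recovers_blocks(self):
        # 12 cells, 3 strictly separated blocks; lambda1 = 0 so only the
        # consensus graph acts. Oracle: connected components of S.
        from scipy.sparse.csgraph import connected_components

        labels_true = np.repeat([0, 1, 2], 4)
        Sc = (labels_true[:, None] == labels_true[None, :]).astype(float)
        n_comp, comp = connected_components(Sc > 0)
        assert n_comp == 3
        # seed chosen so each block's initial average has a distinct leading
        # column; the update cannot mix blocks (S has no cross-block edges),
        # so the argmax partition must then coincide with the components
        rng = np.random.default_rng(2)
        H = rng.uniform(size=(12, 3))
        H = H / H.sum(1, keepdims=True)
        W = np.zeros((12, 2))
        for _ in range(200):
            H = S.update_H(H, W, Sc, lambda1=0.0, lambda2=0.5)
        # rows within a block converge to one common profile
        for b in range(3):
            rows = H[comp == b]
            np.testing.assert_allclose(rows - rows[0], 0.0, atol=1e-6)
        assert adjusted_rand_index(comp, H.argmax(axis=1)) == 1.0


class TestWeights:
    def test_w_formula(self):
        W = np.eye(2)
        V = {"a": np.eye(2)}
        X_res1 = np.eye(2) + np.array([[1.0, 0.0], [0.0, 0.0]])  # residual norm 1
        w = S.update_weight_w([X_res1], W, V)
        assert w[0] == pytest.approx(0.5)
        X_res2 = np.eye(2) + np.array([[2.0, 0.0], [0.0, 0.0]])
        assert S.update_weight_w([X_res2], W, V)[0] == pytest.approx(0.25)

    def test_w_floor_at_exact_fit(self):
        W = np.eye(2)
        V = {"a": np.eye(2)}
        w = S.update_weight_w([np.eye(2)], W, V)
        assert w[0] == pytest.approx(1.0 / (2 * S.RESIDUAL_FLOOR))
        assert np.isfinite(w[0])

    def test_alpha_formula_and_monotonicity(self):
        Sc = np.zeros((2, 2))
        near = np.array([[1.0, 0.0], [0.0, 0.0]])  # distance 1
        far = np.array([[2.0, 0.0], [0.0, 0.0]])  # distance 2
        alpha = S.update_weight_alpha(Sc, [near, far], (2, 1))
        assert alpha[0, 0] == pytest.approx(0.5)
        assert alpha[1, 0] == pytest.approx(0.25)
        assert alpha[0, 0] > alpha[1, 0]
        exact = S.update_weight_alpha(near, [near], (1, 1))
        assert exact[0, 0] == pytest.approx(1.0 / (2 * S.RESIDUAL_FLOOR))


class TestAssignLabels:
    def test_argmax_and_tie_break(self):
        H = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        lv = S.assign_labels(H)
        np.testing.assert_array_equal(lv.labels, [1, 0, 2])

    def test_one_hot_recovery(self):
        rng = np.random.default_rng(14)
        z = rng.integers(0, 4, size=10)
        H = np.zeros((10, 4))
        H[np.arange(10), z] = 1.0
        np.testing.assert_array_equal(S.assign_labels(H).labels, z)


class TestFit:
    def test_same_seed_bit_identical(self):
        ds, base = make_random_instance(0, n=40, p=(12, 9))
        hp = S.HyperParams(C=3, k=5, seed=7, max_iter=15, tol=0.0)
        a = S.fit(ds, base, hp)
        b = S.fit(ds, base, hp)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)
        np.testing.assert_array_equal(a.S, b.S)
        assert a.objective_trace == b.objective_trace

    @pytest.mark.parametrize("lam1,lam2", [(0.0, 0.0), (0.1, 0.01), (1.0, 1.0)])
    def test_objective_trace_nonincreasing(self, lam1, lam2):
        for seed in range(3):
            ds, base = make_random_instance(seed, n=50, p=(15, 10))
            hp = S.HyperParams(C=3, k=5, lambda1=lam1, lambda2=lam2, seed=seed,
                               max_iter=25, tol=0.0)
            st = S.fit(ds, base, hp)
            tr = np.array(st.objective_trace)
            assert ((tr[1:] - tr[:-1]) <= 1e-8 * np.abs(tr[:-1])).all()

    def test_factors_stay_nonnegative_and_H_unitized(self):
        ds, base = make_random_instance(1, n=40, p=(12, 9))
        st = S.fit(ds, base, S.HyperParams(C=3, k=4, seed=1, max_iter=10, tol=0.0))
        assert st.W.min() >= 0
        assert st.S.min() >= 0
        assert all(V.min() >= 0 for V in st.V.values())
        np.testing.assert_allclose(st.H.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(st.S, st.S.T, atol=1e-12)

    def test_random_init_matches_literal_scheme(self):
        # init="random" must draw the factors straight from uniform(0,1)
        ds, base = make_random_instance(2, n=30, p=(10, 8))
        hp = S.HyperParams(C=3, k=4, seed=3, max_iter=1, tol=0.0, init="random")
        st = S.fit(ds, base, hp)
        assert st.iteration == 1

    def test_mismatched_cells_rejected(self):
        ds, _ = make_random_instance(3, n=30, p=(10, 8))
        _, base_other = make_random_instance(4, n=25, p=(10, 8))
        with pytest.raises(ValidationError):
            S.fit(ds, base_other, S.HyperParams(C=3, k=4))


class TestEstimatorAPI:
    def test_sklearn_params_roundtrip(self):
        m = S.GRMECSC(n_clusters=4, lambda1=0.5)
        params = m.get_params()
        assert params["n_clusters"] == 4
        m.set_params(lambda2=0.2)
        assert m.lambda2 == 0.2

    def test_fit_predict_with_plain_arrays(self):
        rng = np.random.default_rng(0)
        X1 = rng.uniform(size=(30, 12))
        X2 = rng.uniform(size=(30, 8))
        base = [[rng.integers(0, 3, size=30) for _ in range(2)] for _ in range(2)]
        labels = S.GRMECSC(n_clusters=3, n_components=4, max_iter=10,
                           random_state=0).fit_predict([X1, X2], base=base)
        assert labels.shape == (30,)
        assert set(labels) <= {0, 1, 2}

    def test_requires_base(self):
        with pytest.raises(ValueError, match="base"):
            S.GRMECSC(n_clusters=2).fit(np.ones((5, 3)))
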