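import numpy as np
import pytest

from trimda import AssociationDataset, RunConfig
from trimda.core import (
    ApgSettings,
    FactorModel,
    FitDiverged,
    HyperParams,
    MaskIndex,
    fit,
    grad_f_D,
    grad_f_factor,
    initialize_model,
    masked_project,
    nuclear_norm,
    objective,
    predict_scores,
    solve_D,
    solve_orthogonal_factor,
    svt_prox,
)
from trimda.similarity import build_laplacian


def random_mask(rng, shape, frac=0.5):
    sel = rng.uniform(size=shape) < frac
    return MaskIndex.from_pairs(
        {(int(i), int(j)) for i, j in zip(*np.nonzero(sel))}
    )


def random_orth(rng, n, r):
    F, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return F


class TestMaskedProject:
    def test_keeps_only_observed(self):
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = masked_project(M, MaskIndex.from_pairs({(0, 0)}))
        np.testing.assert_array_equal(out, [[1, 0], [0, 0]])

    def test_full_mask_is_identity(self, rng):
        M = rng.standard_normal((3, 4))
        np.testing.assert_array_equal(masked_project(M, MaskIndex.full((3, 4))), M)

    def test_empty_mask_zeroes(self, rng):
        M = rng.standard_normal((3, 4))
        out = masked_project(M, MaskIndex.from_pairs(set()))
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            masked_project(np.zeros((2, 2)), MaskIndex.from_pairs({(5, 0)}))


class TestObjective:
    def test_exact_factorization_zero(self):
        A = np.eye(3)
        model = FactorModel(P=np.eye(3), D=A.copy(), Q=np.eye(3))
        hp = HyperParams(0, 0, 0)
        total, parts = objective(A, MaskIndex.full((3, 3)), model, np.zeros((3, 3)), np.zeros((3, 3)), hp)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_zero_core_counts_positives(self, rng):
        A = (rng.uniform(size=(5, 4)) < 0.4).astype(float)
        mask = MaskIndex.from_pairs({(int(i), int(j)) for i, j in zip(*np.nonzero(A))})
        model = FactorModel(P=random_orth(rng, 5, 2), D=np.zeros((2, 2)), Q=random_orth(rng, 4, 2))
        total, parts = objective(A, mask, model, np.zeros((5, 5)), np.zeros((4, 4)), HyperParams(0, 0, 0))
        assert total == pytest.approx(A.sum())

    def test_matches_independent_recomputation(self, rng):
        """Term-by-term recomputation with a separate SVD for the nuclear
        norm, to 1e-10 relative."""
        n_m, n_d, r_m, r_d = 7, 6, 3, 2
        A = rng.uniform(size=(n_m, n_d))
        mask = random_mask(rng, (n_m, n_d))
        P = random_orth(rng, n_m, r_m)
        Q = random_orth(rng, n_d, r_d)
        D = rng.standard_normal((r_m, r_d))
        L_m = rng.standard_normal((n_m, n_m))
        L_m = L_m + L_m.T
        L_d = rng.standard_normal((n_d, n_d))
        L_d = L_d + L_d.T
        hp = HyperParams(0.7, 1.3, 2.1)
        total, parts = objective(A, mask, FactorModel(P, D, Q), L_m, L_d, hp)

        mb = np.zeros((n_m, n_d), dtype=bool)
        for i, j in mask.observed:
            mb[i, j] = True
        resid = np.where(mb, A - P @ D @ Q.T, 0.0)
        expect = (
            (resid**2).sum()
            + 0.7 * np.trace(P.T @ L_m @ P)
            + 1.3 * np.trace(Q.T @ L_d @ Q)
            + 2.1 * np.linalg.svd(D, compute_uv=False).sum()
        )
        assert total == pytest.approx(expect, rel=1e-10)

    def test_nonfinite_rejected(self):
        A = np.full((2, 2), np.nan)
        model = FactorModel(np.eye(2), np.eye(2), np.eye(2))
        with pytest.raises(ValueError, match="nonfinite"):
            objective(A, MaskIndex.full((2, 2)), model, np.zeros((2, 2)), np.zeros((2, 2)), HyperParams())


class TestSvtProx:
    def test_diagonal_soft_threshold(self):
        np.testing.assert_allclose(svt_prox(np.diag([3.0, 1.0]), 2.0), np.diag([1.0, 0.0]), atol=1e-12)

    def test_tau_zero_identity(self, rng):
        M = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(svt_prox(M, 0.0), M)

    def test_matches_svd_oracle_and_minimizes(self, rng):
        """svt_prox solves argmin tau*||D||_* + 1/2||D - M||_F^2: equals
        the soft-thresholded SVD and beats perturbed candidates."""
        M = rng.standard_normal((4, 3))
        tau = 0.7
        out = svt_prox(M, tau)
        U, s, Vt = np.linalg.svd(M)
        oracle = U[:, :3] @ np.diag(np.maximum(s - tau, 0)) @ Vt
        np.testing.assert_allclose(out, oracle, atol=1e-10)

        def prox_obj(D):
            return tau * np.linalg.svd(D, compute_uv=False).sum() + 0.5 * np.sum((D - M) ** 2)

        base = prox_obj(out)
        for _ in range(200):
            pert = out + rng.standard_normal(out.shape) * rng.uniform(1e-4, 0.3)
            assert prox_obj(pert) >= base - 1e-12


class TestGradients:
    def _instance(self, rng, n_m=6, n_d=5, r_m=3, r_d=2):
        A = rng.uniform(size=(n_m, n_d))
        mask = random_mask(rng, (n_m, n_d))
        P = random_orth(rng, n_m, r_m)
        Q = random_orth(rng, n_d, r_d)
        D = rng.standard_normal((r_m, r_d))
        return A, mask, P, D, Q

    @staticmethod
    def _f(A, mask, P, D, Q):
        mb = np.zeros(A.shape, dtype=bool)
        for i, j in mask.observed:
            mb[i, j] = True
        return np.sum(np.where(mb, A - P @ D @ Q.T, 0.0) ** 2)

    def test_zero_residual_zero_gradient(self, rng):
        A, mask, P, D, Q = self._instance(rng)
        A = P @ D @ Q.T  # residual vanishes everywhere
        assert np.abs(grad_f_D(A, mask, P, D, Q)).max() < 1e-12

    def test_full_mask_identity_factors_reduce_to_least_squares(self, rng):
        A = rng.uniform(size=(4, 4))
        D = rng.standard_normal((4, 4))
        g = grad_f_D(A, MaskIndex.full((4, 4)), np.eye(4), D, np.eye(4))
        np.testing.assert_allclose(g, -2 * (A - D), atol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        """Central finite differences of the masked smooth loss validate
        the D, P and Q gradient formulas on random instances."""
        h = 1e-6
        for _ in range(5):
            A, mask, P, D, Q = self._instance(rng)
            for which, X, g in [
                ("D", D, grad_f_D(A, mask, P, D, Q)),
                ("P", P, grad_f_factor(A, mask, P, D, Q, "left")),
                ("Q", Q, grad_f_factor(A, mask, P, D, Q, "right")),
            ]:
                num = np.zeros_like(X)
                for idx in np.ndindex(X.shape):
                    Xp, Xm = X.copy(), X.copy()
                    Xp[idx] += h
                    Xm[idx] -= h
                    if which == "D":
                        fp, fm = self._f(A, mask, P, Xp, Q), self._f(A, mask, P, Xm, Q)
                    elif which == "P":
                        fp, fm = self._f(A, mask, Xp, D, Q), self._f(A, mask, Xm, D, Q)
                    else:
                        fp, fm = self._f(A, mask, P, D, Xp), self._f(A, mask, P, D, Xm)
                    num[idx] = (fp - fm) / (2 * h)
                denom = max(np.linalg.norm(num), 1e-12)
                assert np.linalg.norm(g - num) / denom < 1e-5, which


class TestSolveD:
    def test_full_mask_closed_form(self, rng):
        """With lambda3 = 0 and everything observed the minimizer is
        D = P' A Q exactly (P, Q orthonormal)."""
        A = rng.uniform(size=(8, 7))
        P = random_orth(rng, 8, 3)
        Q = random_orth(rng, 7, 3)
        D = solve_D(A, MaskIndex.full((8, 7)), P, Q, HyperParams(0, 0, 0), ApgSettings(), np.zeros((3, 3)))
        np.testing.assert_allclose(D, P.T @ A @ Q, atol=1e-6)

    def test_large_tau_annihilates(self, rng):
        A = np.zeros((6, 5))
        P = random_orth(rng, 6, 2)
        Q = random_orth(rng, 5, 2)
        D0 = rng.standard_normal((2, 2))
        D = solve_D(A, MaskIndex.full((6, 5)), P, Q, HyperParams(0, 0, 1e4), ApgSettings(), D0)
        assert np.abs(D).max() < 1e-8

    def test_beats_slow_plain_proximal_descent(self, rng):
        """The accelerated solve reaches at least the sub-objective of
        10,000 plain (non-accelerated) proximal steps."""
        n_m, n_d, r = 10, 8, 3
        A = rng.uniform(size=(n_m, n_d))
        mask = random_mask(rng, (n_m, n_d))
        P = random_orth(rng, n_m, r)
        Q = random_orth(rng, n_d, r)
        hp = HyperParams(0, 0, 0.5)
        D0 = np.zeros((r, r))

        mb = np.zeros(A.shape, dtype=bool)
        for i, j in mask.observed:
            mb[i, j] = True

        def sub_obj(D):
            return np.sum(np.where(mb, A - P @ D @ Q.T, 0.0) ** 2) + 0.5 * nuclear_norm(D)

        # independent plain proximal gradient, step 1/2 (Lipschitz bound)
        D_slow = D0.copy()
        for _ in range(10_000):
            resid = np.where(mb, A - P @ D_slow @ Q.T, 0.0)
            D_slow = svt_prox(D_slow + P.T @ resid @ Q, 0.25)

        D_fast = solve_D(A, mask, P, Q, hp, ApgSettings(max_inner=300, inner_tol=1e-12), D0)
        assert sub_obj(D_fast) <= sub_obj(D_slow) + 1e-6

    def test_never_worse_than_init(self, rng):
        A = rng.uniform(size=(6, 5))
        mask = random_mask(rng, (6, 5))
        P = random_orth(rng, 6, 2)
        Q = random_orth(rng, 5, 2)
        hp = HyperParams(0, 0, 1.0)
        D0 = 5 * rng.standard_normal((2, 2))
        mb = np.zeros(A.shape, dtype=bool)
        for i, j in mask.observed:
            mb[i, j] = True

        def sub_obj(D):
            return np.sum(np.where(mb, A - P @ D @ Q.T, 0.0) ** 2) + nuclear_norm(D)

        D = solve_D(A, mask, P, Q, hp, ApgSettings(max_inner=5), D0)
        assert sub_obj(D) <= sub_obj(D0) + 1e-12


class TestSolveOrthogonalFactor:
    def test_procrustes_oracle(self, rng):
        """lambda = 0, full mask: the constrained minimizer is the
        orthogonal Procrustes solution P* = U V' from the SVD of A Q D'."""
        n_m, n_d, r = 10, 8, 3
        D = np.diag(rng.uniform(1, 3, r))
        Q = random_orth(rng, n_d, r)
        A = rng.standard_normal((n_m, n_d))
        mask = MaskIndex.full((n_m, n_d))
        U, _, Vt = np.linalg.svd(A @ Q @ D.T, full_matrices=False)
        P_star = U @ Vt
        P0 = random_orth(rng, n_m, r)
        P, info = solve_orthogonal_factor(
            A, mask, D, Q, np.zeros((n_m, n_m)), 0.0,
            ApgSettings(max_inner=300, inner_tol=1e-12), P0, side="left", return_info=True,
        )
        assert np.linalg.norm(P @ D @ Q.T - P_star @ D @ Q.T) < 1e-5
        assert info["max_orthogonality_drift"] < 1e-8

    def test_orthonormal_b_fixed_point(self, rng):
        """lambda = 0 and the prox target already orthonormal: the solver
        returns it unchanged (it is the exact minimizer)."""
        n, r = 8, 3
        B = random_orth(rng, n, r)
        D = np.eye(r)
        Q = random_orth(rng, 6, r)
        A = B @ D @ Q.T  # gradient at B is zero on the manifold
        P = solve_orthogonal_factor(
            A, MaskIndex.full((n, 6)), D, Q, np.zeros((n, n)), 0.0,
            ApgSettings(), B, side="left",
        )
        np.testing.assert_allclose(P, B, atol=1e-8)

    def test_orthogonality_preserved_throughout(self, rng, small_scenario):
        """Every accepted Cayley iterate stays on the Stiefel manifold."""
        sc = small_scenario
        A = sc.dataset.A
        mask = MaskIndex.full(A.shape)
        L_m = build_laplacian(sc.S_m).L
        model = initialize_model(A, mask, 6, 5, seed=0)
        F, info = solve_orthogonal_factor(
            A, mask, model.D, model.Q, L_m, 10.0, ApgSettings(), model.P,
            side="left", return_info=True,
        )
        assert info["max_orthogonality_drift"] < 1e-8
        assert np.abs(F.T @ F - np.eye(6)).max() < 1e-8

    def test_sub_objective_never_increases(self, rng, small_scenario):
        sc = small_scenario
        A = sc.dataset.A
        mask = MaskIndex.full(A.shape)
        L_d = build_laplacian(sc.S_d).L
        model = initialize_model(A, mask, 6, 5, seed=0)
        _, info = solve_orthogonal_factor(
            A, mask, model.D, model.P, L_d, 7.0, ApgSettings(), model.Q,
            side="right", return_info=True,
        )
        trace = info["trace"]
        assert min(trace) <= trace[0] + 1e-9

    def test_non_orthonormal_init_rejected(self, rng):
        with pytest.raises(ValueError, match="orthonormal"):
            solve_orthogonal_factor(
                np.zeros((4, 4)), MaskIndex.full((4, 4)), np.eye(2),
                random_orth(rng, 4, 2), np.zeros((4, 4)), 0.0, ApgSettings(),
                np.ones((4, 2)), side="left",
            )


class TestInitializeModel:
    def test_identity_matrix(self):
        model = initialize_model(np.eye(3), MaskIndex.full((3, 3)), 3, 3, seed=0)
        sv = np.linalg.svd(model.D, compute_uv=False)
        np.testing.assert_allclose(sv, [1, 1, 1], atol=1e-12)
        # P, Q are signed permutations of I
        assert np.allclose(np.abs(model.P).sum(axis=0), 1)

    def test_zero_matrix_padded(self):
        with pytest.warns(UserWarning, match="padding"):
            model = initialize_model(np.zeros((5, 4)), MaskIndex.full((5, 4)), 2, 2, seed=3)
        np.testing.assert_allclose(model.P.T @ model.P, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(model.D, np.zeros((2, 2)), atol=1e-12)

    def test_orthonormal_for_any_input(self, rng):
        A = rng.uniform(size=(9, 7))
        model = initialize_model(A, MaskIndex.full((9, 7)), 4, 3, seed=0)
        np.testing.assert_allclose(model.P.T @ model.P, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(model.Q.T @ model.Q, np.eye(3), atol=1e-10)

    def test_deterministic(self):
        A = np.zeros((6, 6))
        m1 = initialize_model(A, MaskIndex.full((6, 6)), 3, 3, seed=9)
        m2 = initialize_model(A, MaskIndex.full((6, 6)), 3, 3, seed=9)
        np.testing.assert_array_equal(m1.P, m2.P)
        np.testing.assert_array_equal(m1.Q, m2.Q)


class TestFit:
    def test_objective_trace_non_increasing(self, small_scenario, fast_config):
        sc = small_scenario
        _, trace = fit(sc.dataset, sc.S_m, sc.S_d, fast_config)
        diffs = np.diff(trace)
        assert (diffs <= 1e-9).all()

    def test_no_positives_collapses_to_zero(self, small_scenario, fast_config):
        sc = small_scenario
        empty = AssociationDataset.from_matrix(
            np.zeros_like(sc.dataset.A), sc.dataset.mirna_ids, sc.dataset.disease_ids
        )
        model, _ = fit(empty, sc.S_m, sc.S_d, fast_config)
        assert np.abs(predict_scores(model)).max() < 1e-6

    def test_deterministic_given_seed(self, small_scenario, fast_config):
        sc = small_scenario
        m1, t1 = fit(sc.dataset, sc.S_m, sc.S_d, fast_config)
        m2, t2 = fit(sc.dataset, sc.S_m, sc.S_d, fast_config)
        assert t1 == t2
        np.testing.assert_array_equal(predict_scores(m1), predict_scores(m2))

    def test_unregularized_full_rank_reaches_zero(self, rng):
        """With no regularization and full rank an exact factorization
        exists, and the solver finds it."""
        A = (rng.uniform(size=(12, 10)) < 0.3).astype(float)
        ds = AssociationDataset.from_matrix(
            A, [f"m{i}" for i in range(12)], [f"d{j}" for j in range(10)]
        )
        ids_m, ids_d = ds.mirna_ids, ds.disease_ids
        from trimda.similarity import SimilarityMatrix

        S_m = SimilarityMatrix(ids_m, np.eye(12))
        S_d = SimilarityMatrix(ids_d, np.eye(10))
        cfg = RunConfig(lambda1=0, lambda2=0, lambda3=0, r_m=12, r_d=10, seed=0)
        _, trace = fit(ds, S_m, S_d, cfg)
        assert trace[-1] < 1e-6

    def test_mismatched_similarity_order_rejected(self, small_scenario, fast_config):
        sc = small_scenario
        from trimda.similarity import SimilarityMatrix

        wrong = SimilarityMatrix(list(reversed(sc.S_m.ids)), sc.S_m.S)
        with pytest.raises(ValueError, match="ids do not match"):
            fit(sc.dataset, wrong, sc.S_d, fast_config)

    def test_synthetic_recovery(self, small_scenario, fast_config):
        """On a learnable scenario the fitted scores separate hidden
        positives from negatives and beat the all-zero baseline."""
        from trimda import recovery_report

        sc = small_scenario
        model, _ = fit(sc.dataset, sc.S_m, sc.S_d, fast_config)
        report = recovery_report(sc, model)
        assert report["heldout_auc"] > 0.8
        assert report["rel_error_on_hidden"] < 1.0


class TestPredictScores:
    def test_identity_factors_return_core(self, rng):
        D = rng.standard_normal((4, 4))
        model = FactorModel(np.eye(4), D, np.eye(4))
        np.testing.assert_array_equal(predict_scores(model), D)

    def test_zero_core_zero_scores(self, rng):
        model = FactorModel(random_orth(rng, 5, 2), np.zeros((2, 3)), random_orth(rng, 6, 3))
        np.testing.assert_array_equal(predict_scores(model), np.zeros((5, 6)))

    def test_matches_triple_loop(self, rng):
        P = random_orth(rng, 5, 2)
        D = rng.standard_normal((2, 3))
        Q = random_orth(rng, 4, 3)
        out = predict_scores(FactorModel(P, D, Q))
        naive = np.zeros((5, 4))
        for i in range(5):
            for j in range(4):
                for a in range(2):
                    for b in range(3):
                        naive[i, j] += P[i, a] * D[a, b] * Q[j, b]
        np.testing.assert_allclose(out, naive, atol=1e-12)


class TestRegularizerDirection:
    def test_lambda3_shrinks_nuclear_norm(self, small_scenario):
        """Increasing the nuclear penalty never increases the converged
        nuclear norm of the core (3-point grid)."""
        sc = small_scenario
        norms = []
        for lam3 in [0.1, 1.0, 10.0]:
            cfg = RunConfig(lambda3=lam3, seed=0, solver=ApgSettings(max_inner=30, max_outer=15))
            model, _ = fit(sc.dataset, sc.S_m, sc.S_d, cfg)
            norms.append(nuclear_norm(model.D))
        assert norms[0] >= norms[1] - 1e-6 and norms[1] >= norms[2] - 1e-6

    def test_lambda1_smooths_mirna_factor(self, small_scenario):
        sc = small_scenario
        L_m = build_laplacian(sc.S_m).L
        vals = []
        for lam1 in [0.1, 10.0, 100.0]:
            cfg = RunConfig(lambda1=lam1, seed=0, solver=ApgSettings(max_inner=30, max_outer=15))
            model, _ = fit(sc.dataset, sc.S_m, sc.S_d, cfg)
            vals.append(float(np.trace(model.P.T @ L_m @ model.P)))
        assert vals[0] >= vals[1] - 1e-6 and vals[1] >= vals[2] - 1e-6
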