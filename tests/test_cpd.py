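"""Non-negative CP solver, diagnostics, and their independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls as scipy_nnls

from tmstensor.cpd import (
    CPModel,
    DecomposeConfig,
    Tensor5D,
    congruence,
    corcondia,
    explained_variance,
    khatri_rao,
    mttkrp,
    nncp_als,
    nnls_rows,
    normalize_model,
    sweep_rank,
    unfold,
)

from conftest import random_cp_tensor


class TestNNLSRows:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=5),
        st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_lawson_hanson_objective(self, rank, seed):
        """The active-set enumeration attains the same objective as the
        classic Lawson-Hanson solver on random strictly convex problems."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((rank + 3, rank))
        H = A.T @ A
        B = rng.standard_normal((4, rank)) * 3.0
        X = nnls_rows(H, B)
        L = np.linalg.cholesky(H + 1e-12 * np.eye(rank))
        for i in range(B.shape[0]):
            ref, _ = scipy_nnls(L.T, np.linalg.solve(L, B[i]))
            obj = X[i] @ H @ X[i] - 2 * B[i] @ X[i]
            obj_ref = ref @ H @ ref - 2 * B[i] @ ref
            assert obj <= obj_ref + 1e-8 * max(1.0, abs(obj_ref))
            assert np.all(X[i] >= 0)

    def test_unconstrained_mode_solves_normal_equations(self):
        rng = np.random.default_rng(1)
        H = np.eye(3) * 2.0
        B = rng.standard_normal((5, 3))
        X = nnls_rows(H, B, nonneg=False)
        np.testing.assert_allclose(X, B / 2.0, atol=1e-12)


class TestUnfoldAndMTTKRP:
    def test_unfolding_matches_khatri_rao_identity(self):
        """unfold(CP tensor, n) == F_n @ khatri_rao(others).T — the algebra
        the ALS normal equations rely on."""
        shape, rank = (4, 3, 5, 2), 2
        W, factors = random_cp_tensor(shape, rank, seed=0)
        for mode in range(4):
            others = [factors[m] for m in range(4) if m != mode]
            np.testing.assert_allclose(
                unfold(W, mode), factors[mode] @ khatri_rao(others).T, atol=1e-12
            )
            np.testing.assert_allclose(
                mttkrp(W, factors, mode),
                factors[mode] @ (khatri_rao(others).T @ khatri_rao(others)),
                atol=1e-10,
            )


class TestNNCPALS:
    def test_noiseless_rank1_fit_is_exact(self):
        W, _ = random_cp_tensor((6, 5, 4), 1, seed=2)
        model = nncp_als(W, DecomposeConfig(rank=1, seed=0, tol=1e-12))
        assert model.fit_percent == pytest.approx(100.0, abs=1e-6)

    def test_objective_monotone_every_sweep(self, small_tensor):
        model = nncp_als(small_tensor, DecomposeConfig(rank=3, seed=0))
        diffs = np.diff(model.objective_trace)
        assert np.all(diffs <= 1e-9 * abs(model.objective_trace[0]))

    def test_recovers_generating_factors_at_5pct_noise(self, small_tensor, small_truth):
        model = normalize_model(nncp_als(small_tensor, DecomposeConfig(rank=3, seed=7)))
        truth = CPModel(
            factors=small_truth.factor_list(), rank=3, fit_percent=100.0,
            iterations=0, converged=True,
        )
        C, match = congruence(model, truth)
        for mode in range(5):
            Cm, _ = congruence(model, truth, modes=[mode])
            for p in range(3):
                assert Cm[p, match[p]] >= 0.95

    def test_deterministic_given_seed(self, small_tensor):
        cfg = DecomposeConfig(rank=2, seed=5, n_restarts=2)
        a = nncp_als(small_tensor, cfg)
        b = nncp_als(small_tensor, cfg)
        for fa, fb in zip(a.factors, b.factors):
            np.testing.assert_array_equal(fa, fb)

    def test_all_zero_tensor_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            nncp_als(np.zeros((3, 3, 3)), DecomposeConfig(rank=1))

    def test_fixed_modes_stay_bit_identical(self):
        W, factors = random_cp_tensor((5, 4, 3, 3), 2, seed=3, noise=0.1)
        init = [np.abs(np.random.default_rng(9).standard_normal(f.shape)) for f in factors]
        cfg = DecomposeConfig(rank=2, fixed_modes=(0, 1), init_factors=init, seed=0)
        model = nncp_als(W, cfg)
        assert model.factors[0] is init[0]
        assert model.factors[1] is init[1]
        assert not np.array_equal(model.factors[2], init[2])

    def test_matches_exhaustive_unconstrained_als_on_tiny_tensor(self):
        """Oracle equivalence: with the non-negativity constraint off, the
        solver reaches the fit found by an independent exhaustive
        multi-start unconstrained ALS on a 5x4x3x3x2 tensor."""
        shape, rank = (5, 4, 3, 3, 2), 2
        W, _ = random_cp_tensor(shape, rank, seed=11, noise=0.05)

        def brute_als(seed):
            rng = np.random.default_rng(seed)
            fs = [rng.standard_normal((s, rank)) for s in shape]
            for _ in range(400):
                for m in range(5):
                    others = [fs[o] for o in range(5) if o != m]
                    Z = khatri_rao(others)
                    fs[m] = np.linalg.lstsq(Z, unfold(W, m).T, rcond=None)[0].T
            resid = np.linalg.norm(unfold(W, 0) - fs[0] @ khatri_rao(fs[1:]).T)
            return 100.0 * (1.0 - resid**2 / np.sum(W * W))

        oracle_fit = max(brute_als(s) for s in range(6))
        model = nncp_als(
            W, DecomposeConfig(rank=rank, seed=1, nonneg=False, n_restarts=6,
                               tol=1e-12, max_iterations=800),
        )
        assert model.fit_percent == pytest.approx(oracle_fit, abs=1e-6)


class TestExplainedVariance:
    def test_perfect_and_null_models(self):
        W, factors = random_cp_tensor((5, 4, 3), 2, seed=4)
        exact = CPModel(factors=factors, rank=2, fit_percent=np.nan,
                        iterations=0, converged=True)
        assert explained_variance(exact, W) == pytest.approx(100.0, abs=1e-9)
        null = CPModel(factors=[np.zeros_like(f) for f in factors], rank=2,
                       fit_percent=np.nan, iterations=0, converged=True)
        assert explained_variance(null, W) == pytest.approx(0.0, abs=1e-12)

    def test_truncated_orthogonal_decomposition_matches_brute_force(self):
        """For an orthogonally decomposable rank-3 tensor, a rank-2 model of
        the two largest terms explains 100·(σ1²+σ2²)/Σσ² — computed here by
        direct residual norms."""
        rng = np.random.default_rng(8)
        us = [np.linalg.qr(rng.standard_normal((n, 3)))[0] for n in (6, 5, 4)]
        sigmas = np.array([5.0, 3.0, 2.0])
        W = np.einsum("r,ir,jr,kr->ijk", sigmas, *us)
        model = CPModel(
            factors=[u[:, :2] * np.array([[s ** (1 / 3) for s in sigmas[:2]]])
                     for u in us],
            rank=2, fit_percent=np.nan, iterations=0, converged=True,
        )
        expected = 100.0 * (sigmas[:2] ** 2).sum() / (sigmas**2).sum()
        recon = model.reconstruct()
        brute = 100.0 * (1.0 - np.sum((W - recon) ** 2) / np.sum(W**2))
        assert explained_variance(model, W) == pytest.approx(brute, abs=1e-9)
        assert explained_variance(model, W) == pytest.approx(expected, abs=1e-9)

    def test_zero_tensor_rejected(self):
        model = CPModel(factors=[np.ones((3, 1))] * 3, rank=1,
                        fit_percent=np.nan, iterations=0, converged=True)
        with pytest.raises(ValueError, match="zero-norm"):
            explained_variance(model, np.zeros((3, 3, 3)))


class TestCorcondia:
    def test_exact_model_scores_100(self):
        W, factors = random_cp_tensor((6, 5, 4), 3, seed=5)
        model = CPModel(factors=factors, rank=3, fit_percent=100.0,
                        iterations=0, converged=True)
        assert corcondia(model, W) == pytest.approx(100.0, abs=1e-4)

    def test_compressed_core_equals_dense_least_squares_core(self):
        """Oracle: on a small 6x5x4 tensor the factor-projected core equals
        the dense least-squares core solved via the full Kronecker system."""
        W, _ = random_cp_tensor((6, 5, 4), 2, seed=6, noise=0.3)
        model = nncp_als(W, DecomposeConfig(rank=2, seed=0))
        A, B, C = model.factors
        Z = np.kron(np.kron(A, B), C)  # modes in C-order flattening
        g_dense = np.linalg.lstsq(Z, W.reshape(-1), rcond=None)[0].reshape(2, 2, 2)
        core = W
        for m, f in enumerate(model.factors):
            core = np.moveaxis(np.tensordot(np.linalg.pinv(f), core, axes=(1, m)), 0, m)
        np.testing.assert_allclose(core, g_dense, atol=1e-6)
        ideal = np.zeros((2, 2, 2))
        ideal[[0, 1], [0, 1], [0, 1]] = 1.0
        expected = 100.0 * (1.0 - np.sum((g_dense - ideal) ** 2) / 2.0)
        assert corcondia(model, W) == pytest.approx(expected, abs=1e-6)

    def test_overfactoring_rank2_data_with_rank3_collapses(self):
        W, _ = random_cp_tensor((6, 5, 4), 2, seed=7, noise=0.05)
        m2 = nncp_als(W, DecomposeConfig(rank=2, seed=1))
        m3 = nncp_als(W, DecomposeConfig(rank=3, seed=1))
        assert corcondia(m2, W) > 90.0
        try:
            c3 = corcondia(m3, W)
        except ValueError:
            return  # numerically rank-deficient factors: overfactoring flagged
        assert c3 < 50.0

    def test_rank_deficient_factors_raise(self):
        W, factors = random_cp_tensor((6, 5, 4), 2, seed=8)
        dup = [np.column_stack([f, f[:, 0]]) for f in factors]
        model = CPModel(factors=dup, rank=3, fit_percent=np.nan,
                        iterations=0, converged=True)
        with pytest.raises(ValueError, match="rank-deficient"):
            corcondia(model, W)


class TestNormalizeModel:
    def test_reconstruction_invariant_and_idempotent(self):
        W, _ = random_cp_tensor((5, 4, 3), 2, seed=9, noise=0.1)
        model = nncp_als(W, DecomposeConfig(rank=2, seed=0))
        canon = normalize_model(model)
        np.testing.assert_allclose(
            canon.reconstruct(), model.reconstruct(), rtol=1e-12, atol=1e-12
        )
        again = normalize_model(canon)
        for fa, fb in zip(canon.factors, again.factors):
            np.testing.assert_allclose(fa, fb, atol=1e-14)
        for f in canon.factors[:-1]:
            np.testing.assert_allclose(np.linalg.norm(f, axis=0), 1.0, atol=1e-12)

    def test_scale_moves_to_last_mode(self):
        W, factors = random_cp_tensor((5, 4, 3), 2, seed=10)
        doubled = [np.array(f) for f in factors]
        doubled[0][:, 0] *= 2.0
        model = CPModel(factors=doubled, rank=2, fit_percent=np.nan,
                        iterations=0, converged=True)
        canon = normalize_model(model)
        base = normalize_model(
            CPModel(factors=factors, rank=2, fit_percent=np.nan,
                    iterations=0, converged=True)
        )
        assert canon.factors[-1][:, 0] == pytest.approx(2.0 * base.factors[-1][:, 0])
        np.testing.assert_allclose(canon.factors[0], base.factors[0], atol=1e-12)

    def test_zero_column_raises_in_strict_mode(self):
        factors = [np.ones((4, 2)), np.ones((3, 2)), np.ones((2, 2))]
        factors[1][:, 1] = 0.0
        model = CPModel(factors=factors, rank=2, fit_percent=np.nan,
                        iterations=0, converged=True)
        with pytest.raises(ValueError, match="component 1"):
            normalize_model(model)
        tolerant = normalize_model(model, strict=False)
        assert tolerant.factors[-1][:, 1] == pytest.approx(0.0)


class TestCongruence:
    def test_self_congruence_is_identity(self, small_truth):
        model = CPModel(factors=small_truth.factor_list(), rank=3,
                        fit_percent=np.nan, iterations=0, converged=True)
        C, match = congruence(model, model)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
        np.testing.assert_array_equal(match, [0, 1, 2])

    def test_orthogonal_factors_give_zero_off_diagonal(self):
        us = [np.linalg.qr(np.random.default_rng(0).standard_normal((n, 2)))[0]
              for n in (6, 5, 4)]
        model = CPModel(factors=us, rank=2, fit_percent=np.nan,
                        iterations=0, converged=True)
        C, _ = congruence(model, model)
        assert abs(C[0, 1]) < 1e-10

    def test_matching_recovers_component_permutation(self, small_truth):
        model = CPModel(factors=small_truth.factor_list(), rank=3,
                        fit_percent=np.nan, iterations=0, converged=True)
        perm = [2, 0, 1]
        shuffled = CPModel(
            factors=[f[:, perm] for f in small_truth.factor_list()], rank=3,
            fit_percent=np.nan, iterations=0, converged=True,
        )
        _, match = congruence(model, shuffled)
        # component p of `model` is column perm.index(p) of `shuffled`
        np.testing.assert_array_equal(match, [perm.index(p) for p in range(3)])


class TestSweepRank:
    def test_single_rank_gives_single_row(self, small_tensor):
        table = sweep_rank(small_tensor, ranks=[3],
                           cfg=DecomposeConfig(seed=1, n_restarts=2, tol=1e-6))
        assert isinstance(table, pd.DataFrame)
        assert list(table["rank"]) == [3]

    def test_explained_variance_nondecreasing_and_corcondia_collapses(self):
        """On an exactly rank-3 tensor with well-conditioned factors the
        explained variance rises to 100 at rank 3 and CORCONDIA collapses
        (or the factors go numerically rank-deficient) at rank 4."""
        W, _ = random_cp_tensor((8, 7, 6), 3, seed=12, noise=0.002)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sweep_rank(
                W, ranks=[1, 2, 3, 4],
                cfg=DecomposeConfig(seed=2, n_restarts=3, tol=1e-9),
            )
        ev = table["explained_variance"].to_numpy()
        assert np.all(np.diff(ev) >= -0.5)  # up to restart noise
        assert ev[2] > 99.5
        cc = table["corcondia"].to_numpy()
        assert cc[2] > 90.0
        assert np.isnan(cc[3]) or cc[3] < 50.0

    def test_empty_ranks_rejected(self, small_tensor):
        with pytest.raises(ValueError, match="non-empty"):
            sweep_rank(small_tensor, ranks=[])


def test_tensor5d_validates_labels_and_finiteness():
    values = np.ones((2, 2, 2, 2, 2))
    with pytest.raises(ValueError, match="mode 0"):
        Tensor5D(values=values, channels=["a"], freqs=np.arange(2),
                 times=np.arange(2), subjects=["s1", "s2"],
                 condition_labels=["c1", "c2"])
    bad = np.array(values)
    bad[0, 0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        Tensor5D(values=bad, channels=["a", "b"], freqs=np.arange(2),
                 times=np.arange(2), subjects=["s1", "s2"],
                 condition_labels=["c1", "c2"])
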