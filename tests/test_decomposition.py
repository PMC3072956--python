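"""Sparseness machinery, the active-subspace KKT solver, and decompose."""

import numpy as np
import pytest
from scipy.linalg import null_space

from motifsd import (
    BenchmarkSpec,
    BindingMatrix,
    ExpressionMatrix,
    TFAMatrix,
    decompose,
    detect_active,
    hoyer_sparseness,
    project_sparse,
    simulate,
    solve_active_subspace,
)
from motifsd.decomposition import SparsenessSpec


def random_feasible_vectors(rng, n, l1, l2, count):
    """Random non-negative vectors with exact L1 and L2 norms.

    Independent of the projector: draw Dirichlet points (L1 fixed), then
    move along the line toward/away from the uniform vector to hit L2,
    rejecting draws that leave the simplex.
    """
    out = []
    mid = np.full(n, l1 / n)
    while len(out) < count:
        w0 = rng.dirichlet(np.ones(n), size=count) * l1
        d = w0 - mid
        dd = np.sum(d * d, axis=1)
        ok = dd > 1e-12
        c = float(mid @ mid) - l2 * l2
        disc = -dd * c  # mid @ d = 0 on the simplex direction
        alpha = np.sqrt(np.maximum(disc, 0.0)) / np.where(ok, dd, 1.0)
        w = mid + alpha[:, None] * d
        keep = ok & np.all(w >= 0, axis=1)
        out.extend(w[keep])
    return np.array(out[:count])


class TestHoyerSparseness:
    @pytest.mark.parametrize(
        "v,expected",
        [
            ([0, 0, 1, 0], 1.0),  # one-hot: maximal
            ([2, 2, 2, 2], 0.0),  # constant: minimal
            ([1, 1, 0, 0], 2 - np.sqrt(2)),  # L1=2, L2=sqrt(2), n=4
        ],
    )
    def test_closed_form_values(self, v, expected):
        assert hoyer_sparseness(np.array(v, float)) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            hoyer_sparseness(np.zeros(4))

    def test_matches_formula_on_random_vectors(self, rng):
        for _ in range(200):
            v = rng.normal(size=rng.integers(2, 12))
            expected = (np.sqrt(v.size) - np.abs(v).sum() / np.linalg.norm(v)) / (
                np.sqrt(v.size) - 1
            )
            assert hoyer_sparseness(v) == pytest.approx(expected, abs=1e-12)


class TestProjectSparse:
    def test_two_dim_closed_form(self):
        # roots of t^2 - 6t + 5.5 = 3 +/- sqrt(3.5), order preserved
        out = project_sparse(np.array([3.0, 4.0]), 6.0, 5.0)
        assert out == pytest.approx([3 - np.sqrt(3.5), 3 + np.sqrt(3.5)], abs=1e-9)

    def test_attains_norms_and_idempotent(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            v = rng.normal(size=n) * rng.uniform(0.5, 3)
            l2 = float(np.linalg.norm(v))
            sigma = rng.uniform(0.2, 0.95)
            l1 = SparsenessSpec(sigma).l1_for(l2, n)
            out = project_sparse(v, l1, l2)
            assert np.abs(out).sum() == pytest.approx(l1, abs=1e-9)
            assert np.linalg.norm(out) == pytest.approx(l2, abs=1e-9)
            again = project_sparse(out, l1, l2)
            assert np.allclose(again, out, atol=1e-9)

    def test_feasible_input_is_fixed_point(self):
        v = np.array([1.0, 0.5, 0.0, 0.0])
        out = project_sparse(v, float(np.abs(v).sum()), float(np.linalg.norm(v)))
        assert np.allclose(out, v, atol=1e-12)

    def test_signs_restored(self):
        v = np.array([-3.0, 4.0])
        out = project_sparse(v, 6.0, 5.0)
        assert out[0] < 0 and out[1] > 0

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ValueError):
            project_sparse(np.ones(4), 0.5, 1.0)  # L1 < L2

    def test_optimality_against_random_feasible_vectors(self, rng):
        n = 5
        v = rng.normal(size=n)
        l2 = 1.0
        l1 = 1.6
        out = project_sparse(v, l1, l2)
        d_out = np.linalg.norm(np.abs(out) - np.abs(v))
        W = random_feasible_vectors(rng, n, l1, l2, 10_000)
        d_rand = np.linalg.norm(W - np.abs(v), axis=1)
        assert d_out <= d_rand.min() + 1e-9


class TestDetectActive:
    def test_relative_threshold(self):
        active = detect_active(np.array([1.0, 0.05, 0.2]), tau=0.1)
        assert list(np.nonzero(active)[0]) == [0, 2]

    def test_one_hot_and_constant(self):
        assert list(np.nonzero(detect_active(np.array([0.0, 2.0, 0.0])))[0]) == [1]
        assert detect_active(np.ones(4)).all()  # no separation: all active

    def test_permitted_mask_intersection(self):
        active = detect_active(np.array([1.0, 1.0]), permitted=np.array([True, False]))
        assert list(active) == [True, False]


class TestSolveActiveSubspace:
    def test_identity_unconstrained(self):
        s, flag = solve_active_subspace(np.eye(2), np.array([3.0, -1.0]), np.zeros(2, bool))
        assert np.allclose(s, [3.0, -1.0], atol=1e-12) and flag == "ok"

    def test_minimum_norm_when_all_inactive(self):
        s, _ = solve_active_subspace(np.array([[1.0, 1.0]]), np.array([3.0]), np.ones(2, bool))
        assert np.allclose(s, [1.5, 1.5], atol=1e-10)

    def test_inactive_coordinate_driven_to_zero(self):
        s, _ = solve_active_subspace(
            np.array([[1.0, 2.0]]), np.array([5.0]), np.array([True, False])
        )
        assert np.allclose(s, [0.0, 2.5], atol=1e-10)

    def test_residual_contract(self, rng):
        A = rng.normal(size=(3, 6))
        x = rng.normal(size=3)
        inactive = rng.random(6) < 0.5
        s, flag = solve_active_subspace(A, x, inactive)
        assert flag == "ok"
        assert np.linalg.norm(A @ s - x) <= 1e-8 * np.linalg.norm(x)

    def test_agrees_with_nullspace_qp_oracle(self, rng):
        """Independent oracle: particular solution + explicit null-space
        minimization of the inactive energy."""
        for _ in range(100):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(m, 9))
            A = rng.normal(size=(m, n))
            s_true = rng.normal(size=n)
            x = A @ s_true
            inactive = rng.random(n) < 0.5
            s, flag = solve_active_subspace(A, x, inactive)
            s0 = np.linalg.pinv(A) @ x
            Z = null_space(A)
            if Z.size:
                D = np.diag(np.sqrt(inactive.astype(float)))
                t = np.linalg.lstsq(D @ Z, -D @ s0, rcond=None)[0]
                s_oracle = s0 + Z @ t
            else:
                s_oracle = s0
            obj = float(np.sum(s[inactive] ** 2))
            obj_oracle = float(np.sum(s_oracle[inactive] ** 2))
            assert obj <= obj_oracle + 1e-6
            assert np.linalg.norm(A @ s - x) <= 1e-6 * max(1.0, np.linalg.norm(x))


class TestDecompose:
    def test_zero_expression_gives_zero_strengths(self, rng):
        X = ExpressionMatrix(np.zeros((4, 5)), [f"s{i}" for i in range(4)], [f"g{i}" for i in range(5)])
        A = TFAMatrix(rng.normal(size=(4, 3)), X.sample_ids, ["t1", "t2", "t3"])
        W = BindingMatrix(np.abs(rng.normal(size=(3, 5))), A.tf_ids, X.gene_ids)
        S = decompose(X, A, W)
        assert np.allclose(S.values, 0.0)

    def test_exact_recovery_noise_free(self):
        spec = BenchmarkSpec(m=15, N=80, n=8, K=3, noise_sd=0.0, fp_rate=0.0, fn_rate=0.0, seed=4)
        X, W, truth = simulate(spec)
        A = TFAMatrix(truth.A_true, truth.sample_ids, truth.tf_ids)
        S = decompose(X, A, W)
        assert np.max(np.abs(S.values - truth.S_true)) < 1e-6

    def test_exact_recovery_underdetermined(self):
        """More TFs than samples: the KKT active-subspace path must find the
        sparse truth among infinitely many solutions."""
        rng = np.random.default_rng(11)
        m, n, N = 5, 9, 40
        A = rng.normal(size=(m, n))
        S_true = np.zeros((n, N))
        for g in range(N):
            regs = rng.choice(n, size=2, replace=False)
            S_true[regs, g] = rng.choice([-1, 1], 2) * (rng.gamma(2.0, 1.0, 2) + 0.3)
        X = ExpressionMatrix(A @ S_true, [f"s{i}" for i in range(m)], [f"g{i}" for i in range(N)])
        Am = TFAMatrix(A, X.sample_ids, [f"t{i}" for i in range(n)])
        W = BindingMatrix(np.abs(S_true), Am.tf_ids, X.gene_ids)
        S = decompose(X, Am, W)
        assert np.max(np.abs(S.values - S_true)) < 1e-6

    def test_uninformative_binding_still_ranks_targets(self):
        """All-ones W: reduces to sparseness-projected decomposition with
        better-than-chance target ranking."""
        from motifsd import roc_auc

        spec = BenchmarkSpec(m=15, N=100, n=8, K=2, noise_sd=0.1, fp_rate=0.0, fn_rate=0.0, seed=2)
        X, W, truth = simulate(spec)
        A = TFAMatrix(truth.A_true, truth.sample_ids, truth.tf_ids)
        ones = BindingMatrix(np.ones_like(W.values), W.tf_ids, W.gene_ids)
        S = decompose(X, A, ones, restrict_to_w=False)
        _, macro = roc_auc(S, truth.edges)
        assert macro > 0.5

    def test_motif_initialization_dominance_weak_inequality(self):
        """decompose(W) is never worse on average than decompose(all-ones)
        with the same activities (ties expected when A has full column
        rank, where the constrained solution is unique)."""
        from motifsd import roc_auc

        diffs = []
        for seed in range(3):
            spec = BenchmarkSpec(m=12, N=80, n=6, K=2, noise_sd=0.2, fp_rate=0.15, fn_rate=0.1, seed=seed)
            X, W, truth = simulate(spec)
            A = TFAMatrix(truth.A_true, truth.sample_ids, truth.tf_ids)
            ones = BindingMatrix(np.ones_like(W.values), W.tf_ids, W.gene_ids)
            _, auc_w = roc_auc(decompose(X, A, W), truth.edges)
            _, auc_1 = roc_auc(decompose(X, A, ones, restrict_to_w=False), truth.edges)
            diffs.append(auc_w - auc_1)
        assert np.mean(diffs) >= -1e-9
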