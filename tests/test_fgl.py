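import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import prognet as pn
from prognet.fgl import (
    AdmmOptions,
    _fuse_prox_general,
    fgl_objective,
    fit_fgl,
    select_penalties,
    standardized_covariances,
)
from prognet.synthetic import StudyTable
from prognet.variables import BASELINE_VARS


def brute_force_fgl(S_list, n_list, l1, l2, starts):
    """Independent oracle: generic nonsmooth minimisation of the FGL
    objective over the free entries of the symmetric precision matrices."""
    K, p = len(S_list), S_list[0].shape[0]
    iu = np.triu_indices(p)
    m = len(iu[0])

    def unpack(x):
        thetas = []
        for k in range(K):
            T = np.zeros((p, p))
            T[iu] = x[k * m : (k + 1) * m]
            T = T + T.T - np.diag(np.diag(T))
            thetas.append(T)
        return thetas

    def f(x):
        return fgl_objective(unpack(x), S_list, n_list, l1, l2)

    best = np.inf
    for x0 in starts:
        x = x0
        prev = np.inf
        for _ in range(8):  # alternate direction-set and simplex polish
            r = optimize.minimize(f, x, method="Powell",
                                  options={"xtol": 1e-11, "ftol": 1e-14,
                                           "maxiter": 50000, "maxfev": 500000})
            r = optimize.minimize(f, r.x, method="Nelder-Mead",
                                  options={"xatol": 1e-11, "fatol": 1e-14,
                                           "maxiter": 50000, "maxfev": 500000})
            x = r.x
            if prev - r.fun < 1e-10:
                break
            prev = r.fun
        best = min(best, prev if np.isfinite(prev) else r.fun, r.fun)
    return best


def make_starts(S_list):
    K, p = len(S_list), S_list[0].shape[0]
    iu = np.triu_indices(p)
    ident = np.concatenate([np.eye(p)[iu]] * K)
    inv = np.concatenate([np.linalg.inv(S)[iu] for S in S_list])
    return [ident, inv]


def rand_corr(p, rng):
    A = rng.standard_normal((p, p + 4))
    C = A @ A.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


class TestStandardizedCovariances:
    def make_table(self, X, cols):
        df = pd.DataFrame(X, columns=cols)
        df.insert(0, "study_id", "s1")
        return StudyTable("s1", "train", df)

    def test_hand_computed_correlation(self):
        X = np.array([[1, 2, 0], [2, 4, 1], [3, 6, 1], [4, 8, 0]], dtype=float)
        t = self.make_table(X, ["a", "b", "c"])
        (S,), (n,) = standardized_covariances([t], columns=["a", "b", "c"])
        assert n == 4
        expected = np.corrcoef(X, rowvar=False)
        np.testing.assert_allclose(S, expected, atol=1e-12)
        assert S[0, 1] == pytest.approx(1.0)  # b = 2a exactly

    def test_independent_variable_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4000, 3))
        t = self.make_table(X, ["a", "b", "c"])
        (S,), _ = standardized_covariances([t], columns=["a", "b", "c"])
        assert np.all(np.abs(S[np.triu_indices(3, 1)]) < 0.05)

    def test_zero_variance_errors(self):
        X = np.ones((5, 2))
        X[:, 0] = [1, 2, 3, 4, 5]
        t = self.make_table(X, ["a", "b"])
        with pytest.raises(ValueError, match="'b'.*s1"):
            standardized_covariances([t], columns=["a", "b"])


class TestFitFgl:
    def test_single_group_unpenalised_is_inverse_correlation(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        m = fit_fgl([S], [10], 0.0, 0.0, node_labels=["a", "b"])
        np.testing.assert_allclose(m.precisions[0], np.linalg.inv(S), atol=1e-3)
        assert m.fused_edges[0, 1] == pytest.approx(0.5, abs=1e-3)

    def test_full_shrinkage_gives_empty_network(self):
        rng = np.random.default_rng(1)
        S_list = [rand_corr(4, rng) for _ in range(2)]
        m = fit_fgl(S_list, [50, 60], 1e3, 0.0, node_labels=list("abcd"))
        assert np.allclose(m.fused_edges, 0.0, atol=1e-8)
        for theta in m.precisions:
            off = theta[~np.eye(4, dtype=bool)]
            assert np.allclose(off, 0.0, atol=1e-6)

    def test_strong_fusion_equalises_precisions(self):
        rng = np.random.default_rng(2)
        S_list = [rand_corr(3, rng) for _ in range(3)]
        m = fit_fgl(S_list, [40, 50, 60], 0.0, 1e3, node_labels=list("abc"))
        for k in range(1, 3):
            assert np.max(np.abs(m.precisions[k] - m.precisions[0])) < 1e-3

    @pytest.mark.parametrize("p,K,l1,l2", [
        (2, 1, 0.2, 0.0),
        (2, 2, 0.1, 0.2),
        (3, 1, 0.3, 0.0),
        (3, 2, 0.1, 0.1),
    ])
    def test_admm_matches_generic_minimizer(self, p, K, l1, l2):
        rng = np.random.default_rng(p * 10 + K)
        S_list = [rand_corr(p, rng) for _ in range(K)]
        n_list = [8, 5][:K]
        m = fit_fgl(S_list, n_list, l1, l2, AdmmOptions(tol=1e-8))
        obj = fgl_objective(m.precisions, S_list, n_list, l1, l2)
        oracle = brute_force_fgl(S_list, n_list, l1, l2, make_starts(S_list))
        assert abs(obj - oracle) < 1e-4

    def test_lambda2_zero_equals_independent_fits(self):
        rng = np.random.default_rng(3)
        S_list = [rand_corr(3, rng) for _ in range(2)]
        n_list = [30, 20]
        joint = fit_fgl(S_list, n_list, 2.0, 0.0, AdmmOptions(tol=1e-8))
        for k in range(2):
            single = fit_fgl([S_list[k]], [n_list[k]], 2.0, 0.0, AdmmOptions(tol=1e-8))
            np.testing.assert_allclose(
                joint.precisions[k], single.precisions[0], atol=2e-4
            )

    def test_final_objective_beats_identity_start(self):
        rng = np.random.default_rng(4)
        S_list = [rand_corr(4, rng) for _ in range(2)]
        n_list = [25, 30]
        m = fit_fgl(S_list, n_list, 0.5, 0.5)
        start = fgl_objective([np.eye(4)] * 2, S_list, n_list, 0.5, 0.5)
        final = fgl_objective(m.precisions, S_list, n_list, 0.5, 0.5)
        assert final <= start + 1e-8

    def test_precisions_positive_definite(self):
        rng = np.random.default_rng(5)
        S_list = [rand_corr(5, rng) for _ in range(3)]
        m = fit_fgl(S_list, [40, 40, 40], 1.0, 1.0)
        m.validate()


def test_fused_prox_exact_against_nelder_mead():
    rng = np.random.default_rng(6)
    for K in (3, 4, 5):
        A = rng.standard_normal((K, 6))
        gamma = 0.4
        Z = _fuse_prox_general(A, gamma)

        def obj(z, a):
            o = 0.5 * np.sum((z - a) ** 2)
            for i in range(K):
                for j in range(i + 1, K):
                    o += gamma * abs(z[i] - z[j])
            return o

        for m in range(A.shape[1]):
            r = optimize.minimize(
                obj, A[:, m], args=(A[:, m],), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            assert obj(Z[:, m], A[:, m]) <= r.fun + 1e-8


class TestSelectPenalties:
    def make_gaussian_tables(self, precision, n, K, seed):
        rng = np.random.default_rng(seed)
        cov = np.linalg.inv(precision)
        p = precision.shape[0]
        cols = BASELINE_VARS[:p]
        tables = []
        for k in range(K):
            X = rng.multivariate_normal(np.zeros(p), cov, size=n)
            df = pd.DataFrame(X, columns=cols)
            df.insert(0, "study_id", f"s{k}")
            tables.append(StudyTable(f"s{k}", "train", df))
        return tables

    def test_single_pair_short_circuits(self, tiny_train):
        assert select_penalties(tiny_train, [0.3], [0.1]) == (0.3, 0.1)

    def test_dense_truth_prefers_weak_penalty(self):
        # dense precision: strong conditional dependence everywhere
        # (partial correlation 0.3 on every pair)
        p = 4
        prec = np.full((p, p), -0.3)
        np.fill_diagonal(prec, 1.0)
        tables = self.make_gaussian_tables(prec, n=60, K=2, seed=7)
        l1, l2 = select_penalties(
            tables, [0.01, 10.0], [0.01], folds=3, seed=1,
            columns=BASELINE_VARS[:p],
        )
        assert l1 == 0.01

    def test_deterministic_given_seed(self, tiny_train):
        opts = AdmmOptions(tol=1e-5)
        sub = [StudyTable(t.study_id, t.role, t.data.head(60)) for t in tiny_train]
        a = select_penalties(sub, [2.0, 8.0], [1.0], folds=3, seed=5, options=opts)
        b = select_penalties(sub, [2.0, 8.0], [1.0], folds=3, seed=5, options=opts)
        assert a == b
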