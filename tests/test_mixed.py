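"""Mixed-model fitting checks: dense brute-force oracles for the penalized
normal equations, the coefficient covariance and the REML criterion, plus the
model's structural invariances."""

import math

import numpy as np
import pytest

from pssizer import (
    LongitudinalDataset,
    SplineSpec,
    coef_covariance,
    difference_matrix,
    effective_df,
    fit_fixed_lambda,
    fit_reml,
)
from pssizer.mixed import _Workspace

from conftest import make_longitudinal


def dense_eq3_solve(ws, lam, gamma_b):
    """Direct dense minimizer of ||y - Ba - Zb||^2 + lam a'D'D a + b'b/gamma_b."""
    data, spec = ws.data, ws.spec
    n, N, M = data.n_obs, data.n_subjects, spec.n_basis
    B = ws.designs.B
    Z = np.zeros((n, N))
    Z[np.arange(n), data.subject] = 1.0
    D = difference_matrix(M, spec.diff_order)
    W = np.hstack([B, Z])
    P = np.zeros((M + N, M + N))
    P[:M, :M] = lam * D.T @ D
    P[M:, M:] = np.eye(N) / gamma_b
    sol = np.linalg.solve(W.T @ W + P, W.T @ data.value)
    return sol[:M], sol[M:]


def dense_sigma(ws, fit):
    """Explicit (C' V^-1 C + Dbreve)^-1 with V = sigma_b^2 ZZ' + sigma_eps^2 I."""
    data = ws.data
    n, N, M = data.n_obs, data.n_subjects, ws.M
    Z = np.zeros((n, N))
    Z[np.arange(n), data.subject] = 1.0
    V = fit.vc.sigma2_b * Z @ Z.T + fit.vc.sigma2_eps * np.eye(n)
    C = np.hstack([ws.designs.X, ws.designs.Z_B])
    Db = np.zeros((M, M))
    Db[ws.d :, ws.d :] = np.eye(M - ws.d) / fit.vc.sigma2_u
    return np.linalg.inv(C.T @ np.linalg.solve(V, C) + Db)


def dense_reml_m2ll(ws, s2u, s2b, s2e):
    """Textbook REML -2 log-likelihood with the full marginal covariance."""
    data = ws.data
    n, N = data.n_obs, data.n_subjects
    Z = np.zeros((n, N))
    Z[np.arange(n), data.subject] = 1.0
    X, Zb = ws.designs.X, ws.designs.Z_B
    V = s2u * Zb @ Zb.T + s2b * Z @ Z.T + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XVX, X.T @ Vi)
    y = data.value
    return (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + y @ P @ y
        + (n - X.shape[1]) * math.log(2 * math.pi)
    )


class TestFixedLambdaOracle:
    def test_matches_dense_penalized_solve(self, small_data, small_spec):
        ws = _Workspace(small_data, small_spec)
        fit = ws.fit_fixed_lambda(3.7)
        gamma_b = fit.vc.sigma2_b / fit.vc.sigma2_eps
        a_or, b_or = dense_eq3_solve(ws, 3.7, gamma_b)
        assert np.abs(a_or - fit.a_hat).max() < 1e-8
        assert np.abs(b_or - fit.b).max() < 1e-8

    def test_large_lambda_limit_is_a_straight_line(self, small_data, small_spec):
        fit = fit_fixed_lambda(small_data, small_spec, 1e8)
        x = np.linspace(0, 1, 21)
        g, _ = fit.predict_curve(x)
        resid = g - np.polyval(np.polyfit(x, g, 1), x)
        assert np.abs(resid).max() < 1e-3 * (np.abs(g).max() + 1)

    def test_consistent_with_reml_fit_at_reml_lambda(self, small_data, small_spec):
        fr = fit_reml(small_data, small_spec)
        fx = fit_fixed_lambda(small_data, small_spec, fr.lam)
        x = np.linspace(0, 1, 11)
        assert np.abs(fr.predict_curve(x)[0] - fx.predict_curve(x)[0]).max() < 1e-6

    def test_nonpositive_lambda_rejected(self, small_data, small_spec):
        with pytest.raises(ValueError):
            fit_fixed_lambda(small_data, small_spec, 0.0)


class TestCoefficientCovariance:
    def test_matches_dense_construction(self, small_data, small_spec):
        ws = _Workspace(small_data, small_spec)
        fit = ws.fit_fixed_lambda(2.0)
        assert np.abs(dense_sigma(ws, fit) - coef_covariance(fit)).max() < 1e-8

    def test_symmetric_positive_definite(self, small_data, small_spec):
        S = fit_reml(small_data, small_spec).Sigma
        assert np.abs(S - S.T).max() < 1e-12
        assert np.linalg.eigvalsh(S).min() > 0

    def test_reduces_to_penalized_ls_covariance_without_subject_variance(
        self, small_data, small_spec
    ):
        ws = _Workspace(small_data, small_spec)
        fit = ws.solve(gamma_u=0.5, gamma_b=1e-14, lambda_source="fixed")
        C = np.hstack([ws.designs.X, ws.designs.Z_B])
        D0 = np.diag(np.r_[np.zeros(ws.d), np.full(ws.M - ws.d, 1 / 0.5)])
        expected = fit.vc.sigma2_eps * np.linalg.inv(C.T @ C + D0)
        assert np.abs(expected - fit.Sigma).max() < 1e-6 * np.abs(expected).max()


class TestREML:
    def test_profiled_criterion_matches_dense_formula(self, small_data, small_spec):
        ws = _Workspace(small_data, small_spec)
        fit = ws.fit_fixed_lambda(1.3)
        vc = fit.vc
        dense = dense_reml_m2ll(ws, vc.sigma2_u, vc.sigma2_b, vc.sigma2_eps)
        assert abs(-2 * fit.reml_loglik - dense) < 1e-8 * abs(dense)

    def test_optimum_is_a_stationary_point(self, small_data, small_spec):
        ws = _Workspace(small_data, small_spec)
        fit = ws.fit_reml()
        g_u = math.log(fit.vc.sigma2_u / fit.vc.sigma2_eps)
        g_b = math.log(fit.vc.sigma2_b / fit.vc.sigma2_eps)
        f0 = ws.reml_neg2loglik(g_u, g_b)
        h = 1e-4
        grad = np.array(
            [
                (ws.reml_neg2loglik(g_u + h, g_b) - ws.reml_neg2loglik(g_u - h, g_b)) / (2 * h),
                (ws.reml_neg2loglik(g_u, g_b + h) - ws.reml_neg2loglik(g_u, g_b - h)) / (2 * h),
            ]
        )
        assert np.abs(grad).max() < 1e-3 * max(1.0, abs(f0))

    def test_single_subject_rejected(self):
        data = LongitudinalDataset(
            subject=np.zeros(30, dtype=int),
            time=np.linspace(0, 1, 30),
            value=np.sin(np.linspace(0, 1, 30)),
        )
        with pytest.raises(ValueError, match="subject"):
            fit_reml(data, SplineSpec(n_internal_knots=4))


class TestEffectiveDF:
    def test_limits_and_monotonicity(self, rng):
        # rich design: 300 distinct times so the basis is fully identifiable
        data = make_longitudinal(rng, N=6, n_i=50)
        data = LongitudinalDataset(
            subject=data.subject, time=rng.uniform(0, 1, 300), value=data.value
        )
        spec = SplineSpec(n_internal_knots=8)
        ws = _Workspace(data, spec)
        edfs = [effective_df(ws.fit_fixed_lambda(lam)) for lam in 10.0 ** np.arange(-8, 9, 2)]
        assert all(np.diff(edfs) < 0)  # strictly decreasing in lambda
        assert abs(edfs[-1] - spec.diff_order) < 0.01  # -> d as lambda -> inf
        assert abs(edfs[0] - spec.n_basis) < 0.01  # -> M as lambda -> 0


class TestPredictCurve:
    def test_constant_data_recovers_constant(self, rng):
        data = make_longitudinal(rng, truth=lambda t: np.full_like(t, 7.5), sigma_eps=1e-8, sigma_b=0.0)
        fit = fit_reml(data, SplineSpec(n_internal_knots=8))
        g, se = fit.predict_curve(np.linspace(0, 1, 31))
        assert np.abs(g - 7.5).max() < 1e-6 * 7.5
        assert (se > 0).all()

    def test_prediction_at_data_equals_basis_times_coefficients(self, small_data, small_spec):
        fit = fit_reml(small_data, small_spec)
        g, _ = fit.predict_curve(small_data.time)
        assert np.abs(g - fit.designs.B @ fit.a_hat).max() < 1e-10

    def test_se_shrinks_with_sample_size(self, rng):
        # more subjects shrink the curve uncertainty (the subject-level
        # component sigma_b^2 / N dominates, so growing N is what matters)
        x = np.linspace(0.1, 0.9, 17)
        ses = []
        for N in (20, 200):
            data = make_longitudinal(rng, N=N, n_i=10)
            fit = fit_reml(data, SplineSpec(n_internal_knots=8))
            ses.append(fit.predict_curve(x)[1].mean())
        assert ses[1] < ses[0]


class TestInvariances:
    def test_subject_relabeling_and_record_order(self, small_data, small_spec):
        fit = fit_reml(small_data, small_spec)
        perm = np.random.default_rng(5).permutation(small_data.n_obs)
        relabel = {0: 4, 1: 2, 2: 0, 3: 3, 4: 1}
        shuffled = LongitudinalDataset(
            subject=np.array([relabel[s] for s in small_data.subject[perm]]),
            time=small_data.time[perm],
            value=small_data.value[perm],
        )
        fit2 = fit_reml(shuffled, small_spec)
        x = np.linspace(0, 1, 13)
        assert np.abs(fit.predict_curve(x)[0] - fit2.predict_curve(x)[0]).max() < 1e-6

    def test_constant_shift_moves_curve_only(self, small_data, small_spec):
        fit = fit_reml(small_data, small_spec)
        shifted = LongitudinalDataset(
            subject=small_data.subject, time=small_data.time, value=small_data.value + 11.0
        )
        fit2 = fit_reml(shifted, small_spec)
        x = np.linspace(0, 1, 13)
        assert np.abs(fit2.predict_curve(x)[0] - fit.predict_curve(x)[0] - 11.0).max() < 1e-5
        assert np.abs(fit2.derivative(x)[0] - fit.derivative(x)[0]).max() < 1e-4
        assert abs(fit2.edf - fit.edf) < 1e-3  # numerical optimizer tolerance
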