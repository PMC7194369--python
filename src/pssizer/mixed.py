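"""Penalized-spline regression with a subject random intercept, fit by REML.

The model for longitudinal measurements y_ij on subject i at time x_ij is

    y_ij = g(x_ij) + b_i + eps_ij,   b_i ~ N(0, sigma_b^2),
                                     eps_ij ~ N(0, sigma_eps^2),

with g a P-spline.  In the mixed-model reparameterization the spline part
becomes X beta + Z_B u with u ~ N(0, sigma_u^2 I), so the smoothing parameter
is the variance ratio lambda = sigma_eps^2 / sigma_u^2 and all variance
components can be estimated by REML.  The random intercept b_i induces the
within-subject correlation that ordinary scatterplot smoothers ignore.

The heavy lifting happens in :class:`_Workspace`, which precomputes the
cross-products of the design matrices once per dataset so that refitting at
many fixed smoothing levels (as a SiZer map requires) costs only a small
dense solve per level, independent of the number of records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky

from .basis import (
    DesignMatrices,
    KnotVector,
    PenaltyDecomposition,
    SplineSpec,
    basis_matrix,
    build_knots,
    decompose_penalty,
    deriv_basis_matrix,
    difference_matrix,
    make_designs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LongitudinalDataset",
    "VarianceComponents",
    "FitResult",
    "fit_reml",
    "fit_fixed_lambda",
    "coef_covariance",
    "effective_df",
    "predict_curve",
]

_LOG_GAMMA_BOUNDS = (-25.0, 25.0)


@dataclass(frozen=True)
class LongitudinalDataset:
    """Long-format longitudinal data: one record per (subject, time, value)."""

    subject: np.ndarray  # integer codes 0..N-1
    time: np.ndarray
    value: np.ndarray
    subject_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.subject)
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.value, dtype=float)
        if not (len(s) == len(t) == len(y)):
            raise ValueError("subject, time and value must have equal length")
        if len(t) == 0:
            raise ValueError("dataset is empty")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and values must be finite")

    @property
    def n_obs(self) -> int:
        return len(self.time)

    @property
    def n_subjects(self) -> int:
        return int(np.max(self.subject)) + 1 if len(self.subject) else 0

    @property
    def time_range(self) -> tuple[float, float]:
        return float(np.min(self.time)), float(np.max(self.time))

    @classmethod
    def from_arrays(cls, subject, time, value) -> "LongitudinalDataset":
        """Build a dataset from raw arrays, encoding subjects as categories
        in order of first appearance."""
        subject = np.asarray(subject)
        labels, codes = np.unique(subject, return_inverse=True)
        return cls(
            subject=codes.astype(np.int64),
            time=np.asarray(time, dtype=float),
            value=np.asarray(value, dtype=float),
            subject_labels=labels,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject_col: str = "subject",
        time_col: str = "time",
        value_col: str = "value",
    ) -> "LongitudinalDataset":
        for col in (subject_col, time_col, value_col):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        sub = df[[subject_col, time_col, value_col]].copy()
        sub[time_col] = pd.to_numeric(sub[time_col], errors="coerce")
        sub[value_col] = pd.to_numeric(sub[value_col], errors="coerce")
        ok = sub[time_col].notna() & sub[value_col].notna() & sub[subject_col].notna()
        dropped = int((~ok).sum())
        if dropped:
            logger.info("dropped %d rows with missing or non-numeric fields", dropped)
        sub = sub[ok]
        if len(sub) == 0:
            raise ValueError("no usable rows after dropping missing values")
        return cls.from_arrays(
            sub[subject_col].to_numpy(), sub[time_col].to_numpy(), sub[value_col].to_numpy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        labels = (
            self.subject_labels[self.subject]
            if self.subject_labels is not None
            else self.subject
        )
        return pd.DataFrame({"subject": labels, "time": self.time, "value": self.value})


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components.  lambda = sigma2_eps / sigma2_u is the
    smoothing parameter of the equivalent penalized least-squares problem."""

    sigma2_eps: float
    sigma2_b: float
    sigma2_u: float

    @property
    def lam(self) -> float:
        return self.sigma2_eps / self.sigma2_u


@dataclass
class FitResult:
    """One converged penalized-spline mixed-model fit."""

    spec: SplineSpec
    knots: KnotVector
    decomp: PenaltyDecomposition = field(repr=False)
    designs: DesignMatrices = field(repr=False)
    beta: np.ndarray
    u: np.ndarray
    b: np.ndarray
    a_hat: np.ndarray
    vc: VarianceComponents
    Sigma: np.ndarray = field(repr=False)
    edf: float
    reml_loglik: float
    lambda_source: str  # "reml" or "fixed"
    converged: bool = True
    at_bound: tuple[str, ...] = ()

    @property
    def lam(self) -> float:
        return self.vc.lam

    @property
    def phi(self) -> np.ndarray:
        """Stacked smooth-term coefficients Phi = (beta, u)."""
        return np.concatenate([self.beta, self.u])

    def _smooth_design(self, x_grid: np.ndarray, deriv: bool = False) -> np.ndarray:
        builder = deriv_basis_matrix if deriv else basis_matrix
        B = builder(np.asarray(x_grid, dtype=float), self.knots)
        X = B @ self.decomp.U_0
        Z = (B @ self.decomp.U_plus) / np.sqrt(self.decomp.Lambda_plus)
        return np.hstack([X, Z])

    def predict_curve(self, x_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Population-curve estimate and its pointwise standard error."""
        C = self._smooth_design(x_grid)
        g = C @ self.phi
        se = np.sqrt(np.einsum("ij,jk,ik->i", C, self.Sigma, C))
        return g, se

    def derivative(self, x_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """First-derivative estimate g'(x) and its standard error."""
        C = self._smooth_design(x_grid, deriv=True)
        g = C @ self.phi
        se = np.sqrt(np.einsum("ij,jk,ik->i", C, self.Sigma, C))
        return g, se


class _Workspace:
    """Precomputed sufficient statistics for repeated mixed-model solves.

    All quantities below are expressed in units of sigma_eps^2 through the
    variance ratios gamma_u = sigma_u^2/sigma_eps^2 and
    gamma_b = sigma_b^2/sigma_eps^2; sigma_eps^2 itself is profiled out of
    the REML criterion in closed form.
    """

    def __init__(self, data: LongitudinalDataset, spec: SplineSpec):
        if data.n_subjects < 2:
            raise ValueError(
                "at least 2 subjects are required to identify the "
                "subject-intercept variance"
            )
        self.data = data
        self.spec = spec
        self.knots = build_knots(spec)
        Delta = difference_matrix(spec.n_basis, spec.diff_order)
        self.decomp = decompose_penalty(Delta)
        B = basis_matrix(data.time, self.knots)
        self.designs = make_designs(B, self.decomp)
        self.M = spec.n_basis
        self.d = spec.diff_order
        self.N = data.n_subjects
        self.n = data.n_obs
        if self.n <= self.M:
            raise ValueError(
                f"need more observations ({self.n}) than basis functions ({self.M})"
            )

        T = np.hstack([self.designs.X, self.designs.Z_B])  # n x M, C in the notation
        y = data.value
        g = data.subject
        self.TtT = T.T @ T
        self.Tty = T.T @ y
        self.yty = float(y @ y)
        self.counts = np.bincount(g, minlength=self.N).astype(float)
        # per-subject sums of design rows and responses (Z'T and Z'y)
        self.S = np.zeros((self.N, self.M))
        np.add.at(self.S, g, T)
        self.Zty = np.bincount(g, weights=y, minlength=self.N)
        self._T = T

    # ---- REML criterion ------------------------------------------------

    def _joint_matrix(self, gamma_u: float, gamma_b: float) -> tuple[np.ndarray, np.ndarray]:
        K = self.M + self.N
        A = np.zeros((K, K))
        A[: self.M, : self.M] = self.TtT
        A[: self.M, self.M :] = self.S.T
        A[self.M :, : self.M] = self.S
        idx = np.arange(self.M + self.N)
        A[idx[self.M :], idx[self.M :]] += self.counts
        # prior precisions: none on beta, 1/gamma_u on u, 1/gamma_b on b
        A[idx[self.d : self.M], idx[self.d : self.M]] += 1.0 / gamma_u
        A[idx[self.M :], idx[self.M :]] += 1.0 / gamma_b
        c = np.concatenate([self.Tty, self.Zty])
        return A, c

    def reml_neg2loglik(self, log_gamma_u: float, log_gamma_b: float) -> float:
        """-2 x restricted log-likelihood, profiled over sigma_eps^2."""
        gamma_u, gamma_b = np.exp(log_gamma_u), np.exp(log_gamma_b)
        A, c = self._joint_matrix(gamma_u, gamma_b)
        try:
            L = cholesky(A, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        delta = cho_solve((L, True), c)
        prss = self.yty - c @ delta  # = y' P0 y, the profiled quadratic form
        if prss <= 0:
            return np.inf
        nmp = self.n - self.d
        sigma2 = prss / nmp
        logdetA = 2.0 * np.sum(np.log(np.diag(L)))
        logdetG = (self.M - self.d) * np.log(gamma_u) + self.N * np.log(gamma_b)
        return nmp * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetA + logdetG

    # ---- solving at given variance ratios ------------------------------

    def solve(self, gamma_u: float, gamma_b: float, lambda_source: str) -> FitResult:
        A, c = self._joint_matrix(gamma_u, gamma_b)
        L = cho_factor(A, lower=True)
        delta = cho_solve(L, c)
        beta, u, b = delta[: self.d], delta[self.d : self.M], delta[self.M :]
        prss = self.yty - c @ delta
        nmp = self.n - self.d
        sigma2_eps = float(prss / nmp)

        # smooth-coefficient covariance Sigma = (C'V^-1 C + Dbrk)^-1 with
        # V = sigma_b^2 ZZ' + sigma_eps^2 I applied through the per-subject
        # Woodbury identity (V is never formed densely)
        shrink = gamma_b / (1.0 + gamma_b * self.counts)
        CtVC = self.TtT - self.S.T @ (shrink[:, None] * self.S)
        D0 = np.zeros(self.M)
        D0[self.d :] = 1.0 / gamma_u
        Sigma0 = np.linalg.inv(CtVC + np.diag(D0))
        Sigma0 = 0.5 * (Sigma0 + Sigma0.T)
        Sigma = sigma2_eps * Sigma0
        edf = float(np.trace(Sigma0 @ CtVC))

        a_hat = self.designs.to_coefficients(beta, u)
        vc = VarianceComponents(
            sigma2_eps=sigma2_eps,
            sigma2_b=float(gamma_b * sigma2_eps),
            sigma2_u=float(gamma_u * sigma2_eps),
        )
        m2ll = self.reml_neg2loglik(np.log(gamma_u), np.log(gamma_b))
        return FitResult(
            spec=self.spec,
            knots=self.knots,
            decomp=self.decomp,
            designs=self.designs,
            beta=beta,
            u=u,
            b=b,
            a_hat=a_hat,
            vc=vc,
            Sigma=Sigma,
            edf=edf,
            reml_loglik=-0.5 * m2ll,
            lambda_source=lambda_source,
        )

    # ---- EDF as a function of the smoothing parameter ------------------

    def edf_function(self, gamma_b: float):
        """Return EDF(lambda) for fixed subject-variance ratio gamma_b.

        EDF = trace[(C'V^-1 C + D)^-1 C'V^-1 C] is continuous and strictly
        decreasing in lambda, from the number of identifiable basis
        directions down to the penalty nullspace dimension d.
        """
        shrink = gamma_b / (1.0 + gamma_b * self.counts)
        CtVC = self.TtT - self.S.T @ (shrink[:, None] * self.S)
        mask = np.zeros(self.M)
        mask[self.d :] = 1.0

        def edf(lam: float) -> float:
            A = CtVC + np.diag(lam * mask)
            return float(np.trace(np.linalg.solve(A, CtVC)))

        return edf

    def lambda_for_edf(self, target_edf: float, gamma_b: float) -> float:
        """Invert EDF(lambda) by bracketed root-finding on the log scale."""
        edf = self.edf_function(gamma_b)
        scale = np.trace(self.TtT) / (self.M - self.d)
        lo, hi = np.log(scale * 1e-10), np.log(scale * 1e10)
        e_lo, e_hi = edf(np.exp(lo)), edf(np.exp(hi))
        if target_edf >= e_lo:
            return float(np.exp(lo))
        if target_edf <= e_hi:
            return float(np.exp(hi))
        r = optimize.brentq(
            lambda ll: edf(np.exp(ll)) - target_edf, lo, hi, xtol=1e-10, rtol=1e-12
        )
        return float(np.exp(r))

    # ---- optimizers ----------------------------------------------------

    def fit_reml(self) -> FitResult:
        lo, hi = _LOG_GAMMA_BOUNDS
        starts = [(0.0, 0.0), (4.0, -2.0), (-4.0, 2.0)]
        best = None
        for s in starts:
            res = optimize.minimize(
                lambda v: self.reml_neg2loglik(v[0], v[1]),
                x0=np.array(s),
                method="L-BFGS-B",
                bounds=[(lo, hi), (lo, hi)],
                options={"ftol": 1e-12, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("REML optimization failed to produce a finite criterion")
        at_bound = tuple(
            name
            for name, v in zip(("sigma2_u", "sigma2_b"), best.x)
            if v <= lo + 1e-6 or v >= hi - 1e-6
        )
        if at_bound:
            logger.warning("variance component(s) pinned at bound: %s", at_bound)
        fit = self.solve(np.exp(best.x[0]), np.exp(best.x[1]), "reml")
        fit.converged = bool(best.success) or np.isfinite(best.fun)
        fit.at_bound = at_bound
        return fit

    def fit_fixed_lambda(self, lam: float) -> FitResult:
        if not lam > 0:
            raise ValueError("lambda must be positive")
        lo, hi = _LOG_GAMMA_BOUNDS
        gamma_u = 1.0 / lam
        log_gu = float(np.clip(np.log(gamma_u), lo, hi))
        res = optimize.minimize_scalar(
            lambda lg: self.reml_neg2loglik(log_gu, lg),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        fit = self.solve(np.exp(log_gu), np.exp(res.x), "fixed")
        return fit


# ---- functional interface ----------------------------------------------


def fit_reml(data: LongitudinalDataset, spec: SplineSpec) -> FitResult:
    """Fit the penalized-spline random-intercept model with all variance
    components (hence the smoothing parameter) estimated by REML."""
    return _Workspace(data, spec).fit_reml()


def fit_fixed_lambda(data: LongitudinalDataset, spec: SplineSpec, lam: float) -> FitResult:
    """Fit at a fixed smoothing parameter lambda = sigma_eps^2 / sigma_u^2;
    the error and subject-intercept variances are re-estimated by REML
    conditional on lambda."""
    return _Workspace(data, spec).fit_fixed_lambda(lam)


def coef_covariance(fit: FitResult) -> np.ndarray:
    """Covariance Sigma of the smooth-term coefficients Phi = (beta, u)."""
    return fit.Sigma


def effective_df(fit: FitResult) -> float:
    """Effective degrees of freedom of the smooth: trace of the smoother
    matrix mapping the (subject-decorrelated) response to the fitted curve."""
    return fit.edf


def predict_curve(fit: FitResult, x_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population curve estimate and standard error on a grid."""
    return fit.predict_curve(x_grid)
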