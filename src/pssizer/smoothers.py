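"""Scatterplot-smoother baselines: local linear kernel and smoothing spline.

These are the two classical SiZer engines.  Both treat every record as an
independent observation -- deliberately ignoring within-subject correlation,
which is exactly the deficiency the penalized-spline variant addresses -- and
both are linear smoothers, so their complexity is summarized by the effective
degrees of freedom (EDF), the trace of the hat matrix.  Comparisons across
smoother families are made at matched EDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .bands import classify_codes, simultaneous_quantile
from .maps import SiZerMap

__all__ = [
    "LocalLinearSmoother",
    "SmoothingSpline",
    "edf_of_smoother",
    "match_smoothing_grid",
    "baseline_map",
    "ll_fit",
    "ss_fit",
]


def _compress(x: np.ndarray, y: np.ndarray):
    """Aggregate duplicate x locations: unique x, counts, per-x sums of y and
    y^2 (sufficient statistics for every weighted computation below)."""
    xu, inv = np.unique(np.asarray(x, dtype=float), return_inverse=True)
    cnt = np.bincount(inv).astype(float)
    sy = np.bincount(inv, weights=y)
    syy = np.bincount(inv, weights=np.asarray(y, dtype=float) ** 2)
    return xu, cnt, sy, syy


# ---------------------------------------------------------------------------
# local linear kernel smoother
# ---------------------------------------------------------------------------


class LocalLinearSmoother(BaseEstimator):
    """Gaussian-kernel local linear regression.

    At each evaluation point x the data are fit by weighted least squares on
    a local line a0 + a1 (x_i - x) with weights K((x_i - x)/h); the intercept
    estimates g(x) and the slope g'(x).  Lines are reproduced exactly at any
    bandwidth.

    Parameters
    ----------
    bandwidth : float
        Kernel standard deviation h (> 0), in units of x.
    """

    def __init__(self, bandwidth: float = 1.0):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if len(x) < 2:
            raise ValueError("need at least 2 observations")
        self.xu_, self.cnt_, self.sy_, self.syy_ = _compress(x, y)
        self.n_ = len(x)
        self.edf_ = self._edf()
        return self

    def _moments(self, grid: np.ndarray):
        """Kernel moment sums at each grid point, using compressed data."""
        h = self.bandwidth
        dx = self.xu_[None, :] - np.asarray(grid, dtype=float)[:, None]
        w = np.exp(-0.5 * (dx / h) ** 2) * self.cnt_[None, :]
        S0 = w.sum(1)
        S1 = (w * dx).sum(1)
        S2 = (w * dx**2).sum(1)
        # response moments use per-x sums, so duplicates are handled exactly
        wy = np.exp(-0.5 * (dx / h) ** 2) * self.sy_[None, :]
        T0 = wy.sum(1)
        T1 = (wy * dx).sum(1)
        return dx, w, S0, S1, S2, T0, T1

    def predict(self, X) -> np.ndarray:
        g, _, _, _ = self._solve(np.asarray(X, dtype=float).ravel())
        return g

    def derivative(self, X, return_se: bool = False):
        _, gp, se, _ = self._solve(np.asarray(X, dtype=float).ravel())
        return (gp, se) if return_se else gp

    def _solve(self, grid: np.ndarray):
        dx, w, S0, S1, S2, T0, T1 = self._moments(grid)
        den = S0 * S2 - S1**2
        bad = den <= np.finfo(float).tiny * np.maximum(S0 * S2, 1.0)
        den = np.where(bad, np.nan, den)
        a1 = (S0 * T1 - S1 * T0) / den
        a0 = (S2 * T0 - S1 * T1) / den
        # local residual variance: weighted mean square about the local line,
        # with a Sigma w - 2 Sigma w^2 / Sigma w degrees-of-freedom correction
        h = self.bandwidth
        kw = np.exp(-0.5 * (dx / h) ** 2)
        fit_x = a0[:, None] + a1[:, None] * dx  # local line at each data x
        wr2 = (
            (kw * self.cnt_ * fit_x**2).sum(1)
            - 2 * (kw * fit_x * self.sy_).sum(1)
            + (kw * self.syy_).sum(1)
        )
        w2 = (kw**2 * self.cnt_).sum(1)
        dof = np.maximum(S0 - 2.0 * w2 / np.maximum(S0, np.finfo(float).tiny), 1e-8)
        sigma2 = np.maximum(wr2, 0.0) / dof
        # slope variance of the local weighted least squares fit
        xbar = S1 / S0
        Sw = S2 - S1**2 / S0
        l2 = (w**2 / self.cnt_[None, :] * (dx - xbar[:, None]) ** 2).sum(1) / Sw**2
        se = np.sqrt(sigma2 * l2)
        return a0, a1, se, bad

    def _edf(self) -> float:
        """Trace of the hat matrix of the fitted-value smoother at the data:
        each record contributes K(0) S2 / (S0 S2 - S1^2) at its own x.
        Locations whose kernel window is effectively empty (numerically
        singular local fit) interpolate and contribute one df each."""
        dx, w, S0, S1, S2, _, _ = self._moments(self.xu_)
        den = S0 * S2 - S1**2
        ok = den > np.finfo(float).tiny * np.maximum(S0 * S2, 1.0)
        contrib = np.where(ok, self.cnt_ * S2 / np.where(ok, den, 1.0), 1.0)
        return float(np.sum(contrib))

    def blocks_quantile(self, alpha: float = 0.05) -> float:
        """Row-wise Gaussian quantile by the independent-blocks approximation
        of the classical SiZer: m = range / (2h) effective clusters."""
        rng_x = self.xu_[-1] - self.xu_[0]
        m = max(rng_x / (2.0 * self.bandwidth), 1.0)
        return float(norm.ppf(0.5 * (1.0 + (1.0 - alpha) ** (1.0 / m))))


def ll_fit(x, y, bandwidth: float, x_grid):
    """Local linear estimates (g, g', se(g')) on a grid."""
    sm = LocalLinearSmoother(bandwidth).fit(x, y)
    a0, a1, se, bad = sm._solve(np.asarray(x_grid, dtype=float))
    return a0, a1, se


# ---------------------------------------------------------------------------
# smoothing spline
# ---------------------------------------------------------------------------


class SmoothingSpline(BaseEstimator):
    """Cubic smoothing spline: minimizes sum (y_i - g(x_i))^2 +
    lam * integral g''(x)^2 dx.

    Represented as a penalized regression on a cubic B-spline basis with
    knots at the (optionally thinned) unique data locations; the roughness
    matrix integral B''_j B''_k is computed exactly by two-point Gauss
    quadrature on each inter-knot interval (the second derivatives are
    piecewise linear).  As lam -> infinity the fit tends to the least-squares
    line; as lam -> 0 it interpolates.

    Parameters
    ----------
    lam : float
        Roughness penalty weight (> 0).
    max_knots : int
        Unique x locations beyond this are thinned to quantile-placed knots
        (low-rank approximation for large data).
    """

    def __init__(self, lam: float = 1.0, max_knots: int = 200):
        self.lam = lam
        self.max_knots = max_knots

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        xu, cnt, sy, syy = _compress(x, y)
        if len(xu) < 4:
            raise ValueError("need at least 4 distinct x locations")
        if len(xu) > self.max_knots:
            qs = np.linspace(0, 1, self.max_knots)
            knots = np.unique(np.quantile(xu, qs))
        else:
            knots = xu
        p = 3
        t = np.r_[[knots[0]] * p, knots, [knots[-1]] * p]
        self.t_, self.p_ = t, p
        M = len(t) - p - 1
        self.Omega_, self._U0, self._Up, self._p_null = _roughness_cached(t, p, M)

        Bu = BSpline.design_matrix(xu, t, p, extrapolate=False).toarray()
        Cu = np.hstack([Bu @ self._U0, Bu @ self._Up])
        CtWC = Cu.T @ (cnt[:, None] * Cu)
        pen = np.zeros(M)
        pen[self._p_null :] = self.lam
        A = CtWC + np.diag(pen)
        rhs = Cu.T @ sy
        Ainv = np.linalg.inv(A)
        self.coef_ = Ainv @ rhs  # in the (beta, u) coordinates
        self.edf_ = float(np.einsum("ij,ji->", Ainv, CtWC))
        n = cnt.sum()
        fitted = Cu @ self.coef_
        rss = float(syy.sum() - 2 * fitted @ sy + cnt @ fitted**2)
        dof = max(n - self.edf_, 1.0)
        self.sigma2_ = max(rss, 0.0) / dof
        self.Sigma_ = self.sigma2_ * 0.5 * (Ainv + Ainv.T)
        self.xu_, self.n_ = xu, int(n)
        return self

    def _design(self, grid: np.ndarray, deriv: int = 0) -> np.ndarray:
        grid = np.clip(np.asarray(grid, dtype=float), self.t_[0], self.t_[-1])
        M = len(self.t_) - self.p_ - 1
        spl = BSpline(self.t_, np.eye(M), self.p_)
        if deriv:
            spl = spl.derivative(deriv)
        B = spl(grid)
        return np.hstack([B @ self._U0, B @ self._Up])

    def predict(self, X) -> np.ndarray:
        return self._design(X) @ self.coef_

    def derivative(self, X, return_se: bool = False):
        Cp = self._design(X, deriv=1)
        gp = Cp @ self.coef_
        if not return_se:
            return gp
        se = np.sqrt(np.einsum("ij,jk,ik->i", Cp, self.Sigma_, Cp))
        return gp, se


def _roughness_matrix(t: np.ndarray, p: int, M: int) -> np.ndarray:
    """Exact integral of B''_j B''_k: two-point Gauss per inter-knot interval
    (the second derivatives of cubics are piecewise linear)."""
    spl2 = BSpline(t, np.eye(M), p).derivative(2)
    breaks = np.unique(t)
    a, b = breaks[:-1], breaks[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    gq = 1.0 / np.sqrt(3.0)
    Omega = np.zeros((M, M))
    for s in (-gq, gq):
        D = spl2(mid + s * half)  # (n_int, M)
        Omega += (half[:, None] * D).T @ D
    return Omega


_ROUGHNESS_CACHE: dict[bytes, tuple] = {}


def _roughness_cached(t: np.ndarray, p: int, M: int):
    """Roughness matrix plus its nullspace reparameterization, memoized by
    knot sequence (refitting at many smoothing levels reuses it)."""
    key = t.tobytes()
    hit = _ROUGHNESS_CACHE.get(key)
    if hit is not None:
        return hit
    Omega = _roughness_matrix(t, p, M)
    w_eig, V = np.linalg.eigh(Omega)
    w_eig, V = w_eig[::-1], V[:, ::-1]
    n_pos = int(np.sum(w_eig > 1e-10 * w_eig[0]))
    U0 = V[:, n_pos:]
    Up = V[:, :n_pos] / np.sqrt(w_eig[:n_pos])
    out = (Omega, U0, Up, M - n_pos)
    if len(_ROUGHNESS_CACHE) > 32:
        _ROUGHNESS_CACHE.clear()
    _ROUGHNESS_CACHE[key] = out
    return out


def ss_fit(x, y, lam: float, x_grid, max_knots: int = 200):
    """Smoothing-spline estimates (g, g', se(g')) on a grid."""
    sm = SmoothingSpline(lam, max_knots=max_knots).fit(x, y)
    g = sm.predict(x_grid)
    gp, se = sm.derivative(x_grid, return_se=True)
    return g, gp, se


# ---------------------------------------------------------------------------
# EDF matching across smoother families
# ---------------------------------------------------------------------------


def edf_of_smoother(method: str, param: float, x, y=None) -> float:
    """EDF (hat-matrix trace) of a baseline smoother on data locations x."""
    x = np.asarray(x, dtype=float).ravel()
    if y is None:
        y = np.zeros_like(x)
    if method == "ll":
        return LocalLinearSmoother(param).fit(x, y).edf_
    if method == "ss":
        return SmoothingSpline(param).fit(x, y).edf_
    raise ValueError(f"unknown method {method!r}")


def match_smoothing_grid(
    target_edfs: np.ndarray,
    method: str,
    x,
    y=None,
    tol: float = 0.1,
) -> np.ndarray:
    """Invert EDF -> smoothing value per target (bandwidth h for the local
    linear smoother, penalty lam for the smoothing spline), to within
    ``tol`` EDF.  Unattainable targets are clipped to the attainable range.

    EDF is strictly decreasing in the smoothing value for both families, so
    a bracketed root-finder on the log scale suffices.
    """
    x = np.asarray(x, dtype=float).ravel()
    targets = np.atleast_1d(np.asarray(target_edfs, dtype=float))
    rng_x = x.max() - x.min()
    if method == "ll":
        gaps = np.diff(np.unique(x))
        h_lo = max(rng_x * 2e-3, 0.15 * gaps.min()) if len(gaps) else rng_x * 2e-3
        lo, hi = np.log(h_lo), np.log(rng_x * 50.0)
    elif method == "ss":
        scale = rng_x**3  # natural units of the integral penalty
        lo, hi = np.log(scale * 1e-8), np.log(scale * 1e8)
    else:
        raise ValueError(f"unknown method {method!r}")

    def edf_at(logv: float) -> float:
        return edf_of_smoother(method, float(np.exp(logv)), x, y)

    # EDF is monotone decreasing in the smoothing value, so tabulate once on
    # a log grid and invert by interpolation, refining by bisection only
    # where the interpolated guess misses by more than `tol`
    K = 41
    logv = np.linspace(lo, hi, K)
    edfs = np.array([edf_at(v) for v in logv])
    e_lo, e_hi = edfs[0], edfs[-1]
    out = np.empty(len(targets))
    for i, e in enumerate(targets):
        if e >= e_lo:
            out[i] = np.exp(lo)
            continue
        if e <= e_hi:
            out[i] = np.exp(hi)
            continue
        guess = float(np.interp(e, edfs[::-1], logv[::-1]))
        if abs(edf_at(guess) - e) > tol:
            j = int(np.searchsorted(-edfs, -e))  # edfs decreasing
            guess = optimize.brentq(
                lambda lv: edf_at(lv) - e, logv[j - 1], logv[j], xtol=1e-8
            )
        out[i] = np.exp(guess)
    return out


# ---------------------------------------------------------------------------
# baseline SiZer maps
# ---------------------------------------------------------------------------


def baseline_map(
    x,
    y,
    method: str,
    edf_grid: np.ndarray,
    alpha: float = 0.05,
    r: int = 101,
    n_sim: int = 10_000,
    seed: object = None,
    x_grid: np.ndarray | None = None,
    ll_quantile: str = "blocks",
) -> SiZerMap:
    """SiZer map for a baseline smoother over an EDF-matched smoothing grid.

    The local linear rows use the classical independent-blocks Gaussian
    quantile by default (``ll_quantile='sup'`` switches to the sup-simulation
    quantile on the slope smoother weights); the smoothing-spline rows use
    the same sup-simulation quantile machinery as the penalized-spline map.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x_grid is None:
        x_grid = np.linspace(x.min(), x.max(), r)
    else:
        x_grid = np.asarray(x_grid, dtype=float)
        r = len(x_grid)
    edf_grid = np.asarray(edf_grid, dtype=float)
    params = match_smoothing_grid(edf_grid, method, x, y)
    n_levels = len(params)
    from .maps import _as_seedseq

    children = _as_seedseq(seed).spawn(n_levels)
    colors = np.full((n_levels, r), SiZerMap.MISSING, dtype=np.int16)
    edfs = np.full(n_levels, np.nan)
    qs = np.full(n_levels, np.nan)
    for i, prm in enumerate(params):
        if method == "ll":
            sm = LocalLinearSmoother(prm).fit(x, y)
            a0, a1, se, bad = sm._solve(x_grid)
            if ll_quantile == "blocks":
                q = sm.blocks_quantile(alpha)
            else:
                q = _ll_sup_quantile(sm, x_grid, alpha, n_sim, children[i])
            codes = classify_codes(a1 - q * se, a1 + q * se)
            codes[bad | ~np.isfinite(se)] = 0
        else:
            sm = SmoothingSpline(prm).fit(x, y)
            Cp = sm._design(x_grid, deriv=1)
            gp = Cp @ sm.coef_
            se = np.sqrt(np.einsum("ij,jk,ik->i", Cp, sm.Sigma_, Cp))
            q = simultaneous_quantile(
                sm.Sigma_, Cp, se, alpha=alpha, n_sim=n_sim, rng=children[i]
            )
            codes = classify_codes(gp - q * se, gp + q * se)
        colors[i] = codes
        edfs[i] = sm.edf_
        qs[i] = q
    return SiZerMap(
        lambda_grid=params,
        edf_per_level=edfs,
        x_grid=x_grid,
        colors=colors,
        alpha=alpha,
        seed=seed,
        lambda_reml=None,
        method=method,
        quantiles=qs,
    )


def _ll_sup_quantile(sm: LocalLinearSmoother, x_grid, alpha, n_sim, seed) -> float:
    """Sup-simulation quantile for the local linear slope under independent
    homoscedastic errors: simulate sup |L eps| / se with L the slope smoother
    weights at the compressed data locations."""
    rng = np.random.default_rng(seed)
    dx, w, S0, S1, S2, _, _ = sm._moments(np.asarray(x_grid, dtype=float))
    xbar = S1 / S0
    Sw = S2 - S1**2 / S0
    L = w * (dx - xbar[:, None]) / Sw[:, None]  # r x n_unique slope weights
    Lc = L / np.sqrt(sm.cnt_)[None, :]  # aggregated draws scale by sqrt(count)
    se0 = np.sqrt((L**2 / sm.cnt_[None, :]).sum(1))
    draws = rng.standard_normal((Lc.shape[1], n_sim))
    sup = np.max(np.abs(Lc @ draws) / se0[:, None], axis=0)
    sup.sort()
    from math import ceil

    return float(sup[ceil((1 - alpha) * n_sim) - 1])
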