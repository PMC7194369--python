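"""Simultaneous confidence bands for the first derivative of the fitted curve.

A SiZer map colors time points by the sign of g'(x) wherever that sign is
statistically unambiguous.  Because a map performs this test at every grid
point simultaneously, pointwise intervals would overstate significance; the
band here instead uses the (1 - alpha) quantile of the supremum over the grid
of the standardized deviation |C'_x delta| / se(g'(x)), with delta drawn from
the coefficient distribution N(0, Sigma).  The quantile is approximated by
Monte Carlo simulation and applied symmetrically around the derivative
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .mixed import FitResult

__all__ = [
    "DerivativeBand",
    "simultaneous_quantile",
    "derivative_estimate",
    "derivative_band",
    "classify_codes",
]


@dataclass(frozen=True)
class DerivativeBand:
    """First-derivative estimate with simultaneous limits and sign codes.

    codes are +1 where the whole band lies above zero (significant increase,
    blue), -1 where it lies below (decrease, red) and 0 where it straddles
    zero (purple / indeterminate).
    """

    x_grid: np.ndarray
    gprime_hat: np.ndarray
    se: np.ndarray
    alpha: float
    q: float
    lower: np.ndarray
    upper: np.ndarray
    codes: np.ndarray
    n_sim: int
    seed: object = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.x_grid,
                "est": self.gprime_hat,
                "se": self.se,
                "lower": self.lower,
                "upper": self.upper,
                "code": self.codes,
            }
        )


def classify_codes(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Sign classification of an interval: +1 if entirely positive,
    -1 if entirely negative, else 0."""
    codes = np.zeros(len(lower), dtype=int)
    codes[lower > 0] = 1
    codes[upper < 0] = -1
    return codes


def derivative_estimate(fit: FitResult, x_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """g'(x) = C'_x Phi and its standard error sqrt(C'_x Sigma C'_x')."""
    return fit.derivative(x_grid)


def simultaneous_quantile(
    Sigma: np.ndarray,
    Cprime: np.ndarray,
    se: np.ndarray,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte Carlo quantile of sup_x |C'_x delta| / se(x), delta ~ N(0, Sigma).

    The returned value is the order statistic of rank ceil((1 - alpha) n_sim)
    of the simulated suprema (sorted ascending).  With a single grid point it
    reduces to the ordinary Gaussian quantile (about 1.96 at alpha = 0.05).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(rng)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        # guard tiny negative eigenvalues from finite-precision symmetrization
        w, V = np.linalg.eigh(Sigma)
        if w[-1] <= 0:
            raise np.linalg.LinAlgError("Sigma is not positive definite")
        L = V * np.sqrt(np.clip(w, 0.0, None))
    A = (Cprime @ L) / se[:, None]  # r x M, rows standardized
    draws = rng.standard_normal((L.shape[1], n_sim))
    sup = np.max(np.abs(A @ draws), axis=0)
    sup.sort()
    rank = ceil((1.0 - alpha) * n_sim)
    return float(sup[rank - 1])


def derivative_band(
    fit: FitResult,
    x_grid: np.ndarray,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: object = None,
) -> DerivativeBand:
    """Simultaneous (1 - alpha) band for g' on a grid, with sign codes."""
    x_grid = np.asarray(x_grid, dtype=float)
    Cprime = fit._smooth_design(x_grid, deriv=True)
    gprime = Cprime @ fit.phi
    se = np.sqrt(np.einsum("ij,jk,ik->i", Cprime, fit.Sigma, Cprime))
    q = simultaneous_quantile(fit.Sigma, Cprime, se, alpha=alpha, n_sim=n_sim, rng=seed)
    lower = gprime - q * se
    upper = gprime + q * se
    return DerivativeBand(
        x_grid=x_grid,
        gprime_hat=gprime,
        se=se,
        alpha=alpha,
        q=q,
        lower=lower,
        upper=upper,
        codes=classify_codes(lower, upper),
        n_sim=n_sim,
        seed=seed,
    )
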