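"""B-spline bases, difference penalties and the mixed-model reparameterization.

A P-spline represents a smooth curve g(x) = sum_m a_m B_m(x; p) in a rich
B-spline basis with evenly spaced knots and controls roughness by penalizing
d-th order finite differences of the coefficients, lambda * a' Delta_d' Delta_d a.
Eigendecomposing the penalty splits the coefficient space into an unpenalized
polynomial part (the nullspace of Delta_d, dimension d) and a penalized part,
turning the penalized fit into a linear mixed model: B a = X beta + Z_B u with
u carrying an iid normal prior whose variance ratio is the smoothing parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "KnotVector",
    "PenaltyDecomposition",
    "DesignMatrices",
    "build_knots",
    "basis_matrix",
    "deriv_basis_matrix",
    "difference_matrix",
    "decompose_penalty",
    "make_designs",
]

# relative threshold below which a penalty eigenvalue counts as nullspace
_NULLSPACE_RTOL = 1e-10


@dataclass(frozen=True)
class SplineSpec:
    """Configuration of a P-spline basis.

    Parameters
    ----------
    degree : int
        Polynomial degree p of the B-splines (cubic by default).
    n_internal_knots : int
        Number of evenly spaced knots strictly inside the domain.  Together
        with the two boundary knots this partitions the domain into
        ``n_internal_knots + 1`` segments, giving ``M = n_internal_knots +
        degree + 1`` basis functions (27 cubic B-splines by default) -- large
        enough that the penalty, not the basis size, governs smoothness.
    diff_order : int
        Order d of the difference penalty.  Its nullspace consists of
        degree-(d-1) polynomial coefficient trends; d = 2 (the default)
        shrinks toward straight lines.
    domain_lo, domain_hi : float
        Covariate range spanned by the knots.
    """

    degree: int = 3
    n_internal_knots: int = 23
    diff_order: int = 2
    domain_lo: float = 0.0
    domain_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if self.n_internal_knots < 2:
            raise ValueError(
                f"n_internal_knots must be >= 2, got {self.n_internal_knots}"
            )
        if self.diff_order < 1:
            raise ValueError(f"diff_order must be >= 1, got {self.diff_order}")
        if not (np.isfinite(self.domain_lo) and np.isfinite(self.domain_hi)):
            raise ValueError("domain bounds must be finite")
        if not self.domain_lo < self.domain_hi:
            raise ValueError("domain_lo must be strictly below domain_hi")
        if self.n_basis <= self.diff_order:
            raise ValueError("basis size must exceed the difference order")

    @property
    def n_basis(self) -> int:
        """Number of B-spline basis functions M."""
        return self.n_internal_knots + self.degree + 1


@dataclass(frozen=True)
class KnotVector:
    """Full knot sequence: an even interior grid extended ``degree`` knots
    beyond each boundary (the standard P-spline construction), so that all
    basis functions keep identical shape and the difference penalty has a
    uniform interpretation."""

    knots: np.ndarray
    degree: int

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        p = self.degree
        return float(self.knots[p]), float(self.knots[-p - 1])


@dataclass(frozen=True)
class PenaltyDecomposition:
    """Eigendecomposition of the difference penalty Delta_d' Delta_d.

    ``U = [U_plus, U_0]`` is orthonormal; exactly ``M - d`` eigenvalues are
    strictly positive and the remaining ``d`` (the polynomial nullspace) are
    numerically zero.
    """

    Delta: np.ndarray
    U_plus: np.ndarray
    Lambda_plus: np.ndarray
    U_0: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.Delta.shape[1]

    @property
    def diff_order(self) -> int:
        return self.Delta.shape[1] - self.Delta.shape[0]


@dataclass(frozen=True)
class DesignMatrices:
    """Mixed-model design built from a basis matrix B and a penalty
    decomposition: ``B a = X beta + Z_B u`` with ``beta = U_0' a`` and
    ``u = diag(Lambda_plus)^{1/2} U_plus' a``, so the penalty quadratic form
    becomes ``u'u``."""

    B: np.ndarray
    X: np.ndarray
    Z_B: np.ndarray
    decomp: PenaltyDecomposition = field(repr=False)

    def to_coefficients(self, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Recover spline coefficients a from the mixed-model coordinates."""
        d = self.decomp
        return d.U_0 @ beta + d.U_plus @ (u / np.sqrt(d.Lambda_plus))

    def from_coefficients(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map spline coefficients a to (beta, u)."""
        d = self.decomp
        return d.U_0.T @ a, np.sqrt(d.Lambda_plus) * (d.U_plus.T @ a)


def build_knots(spec: SplineSpec) -> KnotVector:
    """Even knot grid over the spec's domain, extended for degree-p support.

    The interior grid has ``n_internal_knots`` knots strictly between the
    boundary knots at ``domain_lo`` and ``domain_hi``; ``degree`` extra knots
    continue the even spacing beyond each side so the basis is well defined on
    the closed domain (the right endpoint by the limit-from-the-left
    convention).
    """
    p = spec.degree
    n_grid = spec.n_internal_knots + 2  # interior knots plus the two boundaries
    grid = np.linspace(spec.domain_lo, spec.domain_hi, n_grid)
    h = grid[1] - grid[0]
    left = spec.domain_lo - h * np.arange(p, 0, -1)
    right = spec.domain_hi + h * np.arange(1, p + 1)
    return KnotVector(np.concatenate([left, grid, right]), degree=p)


def _check_support(x: np.ndarray, knots: KnotVector) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = knots.domain
    tol = 1e-12 * max(abs(lo), abs(hi), 1.0)
    if np.any(x < lo - tol) or np.any(x > hi + tol):
        raise ValueError(
            f"x outside the knot support [{lo}, {hi}]"
        )
    return np.clip(x, lo, hi)


def basis_matrix(x: np.ndarray, knots: KnotVector, degree: int | None = None) -> np.ndarray:
    """Evaluate the B-spline basis at x; rows sum to one (partition of unity)
    and have at most degree + 1 nonzero entries."""
    p = knots.degree if degree is None else degree
    x = _check_support(np.atleast_1d(x), knots)
    return BSpline.design_matrix(x, knots.knots, p, extrapolate=False).toarray()


def deriv_basis_matrix(x: np.ndarray, knots: KnotVector, degree: int | None = None) -> np.ndarray:
    """First derivatives of the basis functions at x.

    Uses the exact B-spline derivative recurrence
    ``B'_{m,p} = p (B_{m,p-1}/(t_{m+p}-t_m) - B_{m+1,p-1}/(t_{m+p+1}-t_{m+1}))``;
    rows therefore sum to zero.
    """
    p = knots.degree if degree is None else degree
    if p < 1:
        raise ValueError("derivative basis requires degree >= 1")
    t = knots.knots
    x = _check_support(np.atleast_1d(x), knots)
    # degree-(p-1) basis on the same knot sequence has M + 1 functions
    lower = BSpline.design_matrix(x, t, p - 1, extrapolate=False).toarray()
    M = len(t) - p - 1
    m = np.arange(M)
    left = lower[:, :M] / (t[m + p] - t[m])
    right = lower[:, 1 : M + 1] / (t[m + p + 1] - t[m + 1])
    return p * (left - right)


def difference_matrix(M: int, d: int) -> np.ndarray:
    """d-th order finite-difference matrix Delta_d of shape (M - d, M):
    row i applies the d-th difference to coefficient positions i..i+d."""
    if M <= d or d < 1:
        raise ValueError(f"need M > d >= 1, got M={M}, d={d}")
    return np.diff(np.eye(M), n=d, axis=0)


def decompose_penalty(Delta: np.ndarray) -> PenaltyDecomposition:
    """Eigendecompose Delta' Delta into penalized and nullspace directions.

    Eigenvalues are returned non-increasing; those below ``1e-10`` times the
    largest count as the d-dimensional polynomial nullspace.
    """
    Delta = np.asarray(Delta, dtype=float)
    if not np.all(np.isfinite(Delta)):
        raise ValueError("difference matrix contains non-finite entries")
    P = Delta.T @ Delta
    vals, vecs = np.linalg.eigh(P)  # ascending
    vals, vecs = vals[::-1], vecs[:, ::-1]
    d_expected = Delta.shape[1] - Delta.shape[0]
    thresh = _NULLSPACE_RTOL * vals[0]
    n_pos = int(np.sum(vals > thresh))
    if n_pos != Delta.shape[0]:
        raise ValueError(
            f"penalty rank {n_pos} != expected {Delta.shape[0]}; "
            "Delta must have full row rank"
        )
    return PenaltyDecomposition(
        Delta=Delta,
        U_plus=vecs[:, :n_pos],
        Lambda_plus=vals[:n_pos],
        U_0=vecs[:, n_pos : n_pos + d_expected],
    )


def make_designs(B: np.ndarray, decomp: PenaltyDecomposition) -> DesignMatrices:
    """Fixed/random design matrices of the mixed-model representation:
    ``X = B U_0`` (unpenalized polynomial part, n x d) and
    ``Z_B = B U_plus diag(Lambda_plus)^{-1/2}`` (penalized part, n x (M-d))."""
    B = np.asarray(B, dtype=float)
    if B.shape[1] != decomp.n_basis:
        raise ValueError(
            f"B has {B.shape[1]} columns, decomposition expects {decomp.n_basis}"
        )
    X = B @ decomp.U_0
    Z_B = (B @ decomp.U_plus) / np.sqrt(decomp.Lambda_plus)
    return DesignMatrices(B=B, X=X, Z_B=Z_B, decomp=decomp)
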