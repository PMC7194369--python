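"""B-spline basis, difference penalty and reparameterization checks against
independent brute-force oracles (Cox-de Boor recursion, finite differences,
direct matrix algebra)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pssizer import (
    KnotVector,
    SplineSpec,
    basis_matrix,
    build_knots,
    decompose_penalty,
    deriv_basis_matrix,
    difference_matrix,
    make_designs,
)


def cox_de_boor(x, t, m, p):
    """Brute-force recursive definition of B_{m,p}(x) on knot vector t."""
    if p == 0:
        return 1.0 if t[m] <= x < t[m + 1] else 0.0
    out = 0.0
    if t[m + p] > t[m]:
        out += (x - t[m]) / (t[m + p] - t[m]) * cox_de_boor(x, t, m, p - 1)
    if t[m + p + 1] > t[m + 1]:
        out += (t[m + p + 1] - x) / (t[m + p + 1] - t[m + 1]) * cox_de_boor(x, t, m + 1, p - 1)
    return out


class TestKnots:
    def test_even_interior_spacing(self):
        kv = build_knots(SplineSpec(degree=1, n_internal_knots=3, domain_lo=0, domain_hi=1))
        # 3 interior knots plus boundaries: 0, .25, .5, .75, 1
        inner = kv.knots[1:-1]
        assert np.allclose(np.diff(inner), 0.25)
        assert kv.domain == (0.0, 1.0)

    def test_default_gives_27_cubic_basis_functions(self):
        spec = SplineSpec()
        assert spec.n_basis == 27
        kv = build_knots(spec)
        assert kv.n_basis == 27

    @pytest.mark.parametrize("bad", [
        dict(domain_lo=np.nan),
        dict(domain_lo=2.0, domain_hi=1.0),
        dict(n_internal_knots=1),
        dict(degree=0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            SplineSpec(**bad)


class TestBasisMatrix:
    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_matches_cox_de_boor_recursion(self, p, rng):
        kv = build_knots(SplineSpec(degree=p, n_internal_knots=5, domain_lo=0, domain_hi=1))
        x = rng.uniform(0, 0.999, 15)
        B = basis_matrix(x, kv)
        oracle = np.array(
            [[cox_de_boor(xi, kv.knots, m, p) for m in range(kv.n_basis)] for xi in x]
        )
        assert np.abs(B - oracle).max() < 1e-10

    def test_degree_zero_is_indicator(self):
        kv = KnotVector(np.linspace(0, 1, 6), degree=0)
        B = basis_matrix(np.array([0.05, 0.45, 0.85]), kv)
        assert B.shape == (3, 5)
        assert np.all(B.sum(axis=1) == 1.0)
        assert np.all((B == 0) | (B == 1))

    def test_right_endpoint_is_well_defined(self):
        kv = build_knots(SplineSpec())
        B = basis_matrix(np.array([1.0]), kv)
        assert np.isfinite(B).all()
        assert abs(B.sum() - 1.0) < 1e-12

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_partition_of_unity(self, xs):
        kv = build_knots(SplineSpec())
        B = basis_matrix(np.array(xs), kv)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-12
        # local support: at most p + 1 nonzeros per row
        assert (np.count_nonzero(B, axis=1) <= 4).all()

    def test_outside_support_raises(self):
        kv = build_knots(SplineSpec())
        with pytest.raises(ValueError):
            basis_matrix(np.array([1.5]), kv)


class TestDerivativeBasis:
    def test_rows_sum_to_zero(self, rng):
        kv = build_knots(SplineSpec())
        Bp = deriv_basis_matrix(rng.uniform(0, 1, 30), kv)
        assert np.abs(Bp.sum(axis=1)).max() < 1e-10

    def test_matches_central_finite_differences(self, rng):
        kv = build_knots(SplineSpec())
        x = rng.uniform(0.01, 0.99, 40)  # interior: central differences valid
        h = 1e-6
        fd = (basis_matrix(x + h, kv) - basis_matrix(x - h, kv)) / (2 * h)
        assert np.abs(fd - deriv_basis_matrix(x, kv)).max() < 1e-4

    def test_reproduces_linear_slope(self):
        kv = build_knots(SplineSpec())
        x = np.linspace(0, 1, 50)
        B = basis_matrix(x, kv)
        a, *_ = np.linalg.lstsq(B, 2.0 * x, rcond=None)
        slope = deriv_basis_matrix(x, kv) @ a
        assert np.abs(slope - 2.0).max() < 1e-8

    def test_degree_zero_rejected(self):
        kv = KnotVector(np.linspace(0, 1, 6), degree=0)
        with pytest.raises(ValueError):
            deriv_basis_matrix(np.array([0.5]), kv)


class TestDifferencePenalty:
    def test_first_and_second_order_forms(self):
        assert np.array_equal(difference_matrix(3, 1), [[-1, 1, 0], [0, -1, 1]])
        assert np.array_equal(difference_matrix(4, 2), [[1, -2, 1, 0], [0, 1, -2, 1]])

    def test_penalty_rank_is_m_minus_d(self):
        D = difference_matrix(10, 2)
        assert np.linalg.matrix_rank(D.T @ D) == 8

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            difference_matrix(2, 2)

    def test_decomposition_reconstructs_penalty(self):
        D = difference_matrix(27, 2)
        dec = decompose_penalty(D)
        U = np.hstack([dec.U_plus, dec.U_0])
        lam = np.concatenate([dec.Lambda_plus, np.zeros(2)])
        P = U @ np.diag(lam) @ U.T
        assert np.abs(P - D.T @ D).max() < 1e-10
        assert np.abs(U.T @ U - np.eye(27)).max() < 1e-10

    def test_exactly_25_positive_eigenvalues_for_default_basis(self):
        dec = decompose_penalty(difference_matrix(27, 2))
        assert len(dec.Lambda_plus) == 25
        assert dec.U_0.shape == (27, 2)
        assert (dec.Lambda_plus > 0).all()
        assert (np.diff(dec.Lambda_plus) <= 1e-12).all()  # non-increasing

    def test_second_difference_annihilates_linear_trend(self):
        D = difference_matrix(12, 2)
        line = np.arange(1.0, 13.0)
        assert np.abs(D @ line).max() < 1e-12


class TestMixedModelDesigns:
    @pytest.fixture
    def designs(self, rng):
        spec = SplineSpec()
        kv = build_knots(spec)
        B = basis_matrix(rng.uniform(0, 1, 60), kv)
        dec = decompose_penalty(difference_matrix(spec.n_basis, 2))
        return B, dec, make_designs(B, dec)

    def test_round_trip_identity_on_random_coefficients(self, designs, rng):
        B, dec, des = designs
        D = dec.Delta
        worst_fit, worst_pen = 0.0, 0.0
        for _ in range(100):
            a = rng.normal(size=27)
            beta, u = des.from_coefficients(a)
            worst_fit = max(worst_fit, np.abs(B @ a - des.X @ beta - des.Z_B @ u).max())
            worst_pen = max(worst_pen, abs(a @ D.T @ D @ a - u @ u))
            assert np.abs(des.to_coefficients(beta, u) - a).max() < 1e-10
        assert worst_fit < 1e-9
        assert worst_pen < 1e-9 * 27  # relative to ||a||^2 ~ M

    def test_zero_and_nullspace_coefficients(self, designs):
        B, dec, des = designs
        beta, u = des.from_coefficients(np.zeros(27))
        assert np.all(beta == 0) and np.all(u == 0)
        line = np.linspace(-1, 1, 27)  # in the d=2 penalty nullspace
        _, u_line = des.from_coefficients(line)
        assert np.abs(u_line).max() < 1e-12

    def test_dimension_mismatch_rejected(self, designs):
        _, dec, _ = designs
        with pytest.raises(ValueError):
            make_designs(np.zeros((5, 11)), dec)
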