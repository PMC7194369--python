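"""Scikit-learn style estimators wrapping the penalized-spline machinery.

`PenalizedSplineMixedModel` is a regressor for longitudinal data (fit takes
`groups`, the subject labels); `PSSiZer` fits the whole scale-space map and
exposes the feature and durability summaries as fitted attributes.  Both
follow sklearn conventions (constructor stores hyper-parameters unchanged,
fitted state carries a trailing underscore, `get_params`/`set_params` work),
so they compose with sklearn model-selection utilities where that makes
sense.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .bands import derivative_band
from .basis import SplineSpec
from .maps import detect_plateau, feature_summary
from .mixed import LongitudinalDataset, _Workspace

__all__ = ["PenalizedSplineMixedModel", "PSSiZer"]


def _as_times(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single time column")
        X = X[:, 0]
    return X


def _make_dataset(X, y, groups) -> LongitudinalDataset:
    t = _as_times(X)
    y = np.asarray(y, dtype=float).ravel()
    if groups is None:
        raise ValueError(
            "groups (subject identifiers) are required: the model includes a "
            "subject random intercept"
        )
    return LongitudinalDataset.from_arrays(np.asarray(groups), t, y)


class PenalizedSplineMixedModel(RegressorMixin, BaseEstimator):
    """Penalized-spline regression with a subject random intercept.

    Parameters
    ----------
    degree : int
        B-spline degree p.
    n_internal_knots : int
        Evenly spaced knots strictly inside the time range.
    diff_order : int
        Order d of the coefficient difference penalty.
    lam : float or "reml"
        Smoothing parameter; "reml" estimates it together with the variance
        components by restricted maximum likelihood.
    domain : (float, float) or None
        Knot span; defaults to the observed time range.

    Attributes (after fit)
    ----------------------
    coef_ : spline coefficients a
    beta_, u_, b_ : mixed-model coefficients and subject intercepts (BLUPs)
    variance_components_ : VarianceComponents (sigma2_eps, sigma2_b, sigma2_u)
    lambda_ : smoothing parameter used
    Sigma_ : covariance of the smooth-term coefficients (beta, u)
    edf_ : effective degrees of freedom of the smooth
    """

    def __init__(
        self,
        degree: int = 3,
        n_internal_knots: int = 23,
        diff_order: int = 2,
        lam="reml",
        domain: tuple[float, float] | None = None,
    ):
        self.degree = degree
        self.n_internal_knots = n_internal_knots
        self.diff_order = diff_order
        self.lam = lam
        self.domain = domain

    def _spec(self, t: np.ndarray) -> SplineSpec:
        lo, hi = self.domain if self.domain is not None else (t.min(), t.max())
        return SplineSpec(
            degree=self.degree,
            n_internal_knots=self.n_internal_knots,
            diff_order=self.diff_order,
            domain_lo=float(lo),
            domain_hi=float(hi),
        )

    def fit(self, X, y, groups=None):
        data = _make_dataset(X, y, groups)
        ws = _Workspace(data, self._spec(data.time))
        if self.lam == "reml":
            fit = ws.fit_reml()
        else:
            fit = ws.fit_fixed_lambda(float(self.lam))
        self.fit_result_ = fit
        self.workspace_ = ws
        self.coef_ = fit.a_hat
        self.beta_, self.u_, self.b_ = fit.beta, fit.u, fit.b
        self.variance_components_ = fit.vc
        self.lambda_ = fit.lam
        self.Sigma_ = fit.Sigma
        self.edf_ = fit.edf
        self.reml_loglik_ = fit.reml_loglik
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Population-curve prediction g(x) (no subject intercept)."""
        check_is_fitted(self, "fit_result_")
        g, _ = self.fit_result_.predict_curve(_as_times(X))
        return g

    def predict_curve(self, X):
        """(g, se) on a grid."""
        check_is_fitted(self, "fit_result_")
        return self.fit_result_.predict_curve(_as_times(X))

    def derivative(self, X):
        """(g', se) on a grid."""
        check_is_fitted(self, "fit_result_")
        return self.fit_result_.derivative(_as_times(X))


class PSSiZer(BaseEstimator):
    """Penalized-spline SiZer map estimator.

    Fitting builds the full significance map over a ladder of smoothing
    levels (``ladder='lambda'``: log10(lambda_REML) +- span_decades;
    ``ladder='edf'``: evenly spaced effective degrees of freedom) and the
    derivative band at the REML-optimal level.

    Attributes (after fit)
    ----------------------
    map_ : SiZerMap
    reml_fit_ : FitResult at the REML optimum
    lambda_reml_ : REML smoothing parameter
    features_ : FeatureSummary (per-level and map-wide counts)
    durability_ : DurabilityEstimate at the REML level
    """

    def __init__(
        self,
        degree: int = 3,
        n_internal_knots: int = 23,
        diff_order: int = 2,
        alpha: float = 0.05,
        n_levels: int = 100,
        grid_size: int = 101,
        n_sim: int = 10_000,
        span_decades: float = 2.0,
        ladder: str = "lambda",
        random_state: int | None = None,
    ):
        self.degree = degree
        self.n_internal_knots = n_internal_knots
        self.diff_order = diff_order
        self.alpha = alpha
        self.n_levels = n_levels
        self.grid_size = grid_size
        self.n_sim = n_sim
        self.span_decades = span_decades
        self.ladder = ladder
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        from .maps import build_map  # local import to avoid cycle at module load

        data = _make_dataset(X, y, groups)
        spec = SplineSpec(
            degree=self.degree,
            n_internal_knots=self.n_internal_knots,
            diff_order=self.diff_order,
            domain_lo=float(data.time.min()),
            domain_hi=float(data.time.max()),
        )
        map_, reml_fit = build_map(
            data,
            spec,
            alpha=self.alpha,
            n_levels=self.n_levels,
            r=self.grid_size,
            n_sim=self.n_sim,
            seed=self.random_state,
            span_decades=self.span_decades,
            ladder=self.ladder,
            return_reml_fit=True,
        )
        self.map_ = map_
        self.reml_fit_ = reml_fit
        self.lambda_reml_ = reml_fit.lam
        self.features_ = feature_summary(map_)
        band = derivative_band(
            reml_fit,
            map_.x_grid,
            alpha=self.alpha,
            n_sim=self.n_sim,
            seed=self.random_state,
        )
        self.reml_band_ = band
        self.durability_ = detect_plateau(band, lambda_used=reml_fit.lam)
        return self
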