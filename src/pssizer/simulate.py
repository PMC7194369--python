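"""Synthetic longitudinal data generators and the replicate comparison runner.

Two benchmark designs exercise feature detection and plateau detection:

* ``study1`` -- a damped oscillation, f(x) = 65 + 25 exp(-2x) sin(5 pi (x+5))
  on [0, 1].  The sine contributes five sign changes of f' (five "features");
  the exponential envelope shrinks the later ones so they are progressively
  harder to flag against noise.
* ``study2`` -- a rise-then-plateau curve, f(x) = 85 - x/4 - exp(-(x - 4.5))
  on [1, 20), whose derivative crosses zero exactly once, at
  x = 4.5 + ln 4 ~ 5.886.

Both add a subject random intercept b_i ~ N(0, sigma_b^2) and iid noise
eps_ij ~ N(0, sigma_eps^2) to a balanced design of N subjects observed at
n_i shared, equally spaced times.

A third generator emulates body-weight trajectories after treatment start:
a smooth rise whose derivative hits zero exactly at a known plateau week,
irregular exponential visit gaps, and subject-level intercepts.  It provides
ground truth for the durability (plateau-time) pipeline, standing in for
confidential cohort data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .bands import derivative_band
from .basis import SplineSpec
from .maps import (
    SiZerMap,
    _plateau_from_codes,
    build_map,
    detect_plateau,
    feature_summary,
)
from .mixed import LongitudinalDataset
from .smoothers import baseline_map

logger = logging.getLogger(__name__)

__all__ = [
    "SimDesign",
    "ComparisonResult",
    "truth_study1",
    "truth_study1_deriv",
    "truth_study2",
    "truth_study2_deriv",
    "study2_plateau_location",
    "generate",
    "generate_weightlike",
    "run_comparison",
]


def truth_study1(x):
    """Damped oscillation with five interior sign changes of the derivative."""
    x = np.asarray(x, dtype=float)
    return 65.0 + 25.0 * np.exp(-2.0 * x) * np.sin(5.0 * np.pi * (x + 5.0))


def truth_study1_deriv(x):
    x = np.asarray(x, dtype=float)
    e = 25.0 * np.exp(-2.0 * x)
    arg = 5.0 * np.pi * (x + 5.0)
    return e * (-2.0 * np.sin(arg) + 5.0 * np.pi * np.cos(arg))


def truth_study2(x):
    """Monotone rise to a plateau at x = 4.5 + ln 4, then a slow decline."""
    x = np.asarray(x, dtype=float)
    return 85.0 - x / 4.0 - np.exp(-x + 4.5)


def truth_study2_deriv(x):
    x = np.asarray(x, dtype=float)
    return -0.25 + np.exp(-x + 4.5)


def study2_plateau_location(xtol: float = 1e-10) -> float:
    """Stationary point of the study2 truth, located by root-finding on its
    derivative over the design interval (analytically 4.5 + ln 4)."""
    return float(optimize.brentq(truth_study2_deriv, 1.0, 20.0, xtol=xtol))


@dataclass(frozen=True)
class SimDesign:
    """A balanced longitudinal simulation design."""

    design_id: str = "study1"
    N: int = 100
    n_i: int = 10
    sigma2_eps: float = 5.0
    sigma2_b: float = 2.0
    jitter: bool = False

    def __post_init__(self) -> None:
        if self.design_id not in ("study1", "study2"):
            raise ValueError(f"unknown design {self.design_id!r}")
        if self.N < 2 or self.n_i < 2:
            raise ValueError("need N >= 2 subjects and n_i >= 2 visits")
        if self.sigma2_eps < 0 or self.sigma2_b < 0:
            raise ValueError("variances must be non-negative")

    @property
    def interval(self) -> tuple[float, float]:
        """Half-open design interval the visit times fill."""
        return (0.0, 1.0) if self.design_id == "study1" else (1.0, 20.0)

    def times(self, rng: np.random.Generator) -> np.ndarray:
        """Visit times, shape (N, n_i): n_i equally spaced times on the
        half-open design interval, shared by all subjects (the balanced
        reading of the designs).  With ``jitter=True`` each subject's grid is
        instead offset by an independent uniform phase of up to one spacing,
        so the pooled times fill the interval irregularly (as clinic visits
        do) and subject-level heterogeneity acts as local noise for
        smoothers that ignore it -- a robustness variant, off by default."""
        lo, hi = self.interval
        if self.design_id == "study1":
            # closed interval: endpoints included, so the last feature of the
            # damped oscillation (near x = 0.89) is bracketed by data
            base = np.linspace(lo, hi, self.n_i)
            step = (hi - lo) / (self.n_i - 1)
        else:
            # half-open [1, 20): x_j = 1 + 19 j / n_i
            step = (hi - lo) / self.n_i
            base = lo + step * np.arange(self.n_i)
        phase = rng.uniform(0.0, 1.0, self.N) if self.jitter else np.zeros(self.N)
        t = base[None, :] + step * phase[:, None]
        return np.minimum(t, hi)

    @property
    def truth(self):
        return truth_study1 if self.design_id == "study1" else truth_study2

    @property
    def spec(self) -> SplineSpec:
        lo, hi = self.interval
        return SplineSpec(domain_lo=lo, domain_hi=hi)


def generate(design: SimDesign, seed: object = None) -> LongitudinalDataset:
    """y_ij = f(x_ij) + b_i + eps_ij on the design's phase-offset time grids."""
    rng = np.random.default_rng(seed)
    t = design.times(rng)
    f = design.truth(t)
    b = rng.normal(0.0, np.sqrt(design.sigma2_b), design.N)
    eps = rng.normal(0.0, np.sqrt(design.sigma2_eps), (design.N, design.n_i))
    y = f + b[:, None] + eps
    subject = np.repeat(np.arange(design.N), design.n_i)
    return LongitudinalDataset(
        subject=subject,
        time=t.ravel(),
        value=y.ravel(),
    )


# ---------------------------------------------------------------------------
# weight-trajectory emulator
# ---------------------------------------------------------------------------


def _weight_curve(t, baseline, gain, plateau_week, shoulder, decline_slope):
    """Population weight curve: constant-rate rise with a smooth shoulder of
    width ``shoulder`` ending exactly at ``plateau_week`` (the derivative is
    c for t <= T - shoulder, falls linearly to 0 at T), then an optional
    linear decline.  The derivative-zero time is exactly ``plateau_week``."""
    t = np.asarray(t, dtype=float)
    T, tau = plateau_week, shoulder
    c = gain / (T - tau / 2.0)  # rate making the total rise equal `gain`
    # integral of the derivative c * min(1, (T - t)/tau)_+ :
    # linear up to T - tau, then a quadratic shoulder, then flat
    u = np.clip(t - (T - tau), 0.0, tau)
    rise = c * (np.minimum(t, T - tau) + u - u**2 / (2.0 * tau))
    return baseline + rise - decline_slope * np.clip(t - T, 0.0, None)


def _weight_deriv(t, gain, plateau_week, shoulder, decline_slope):
    t = np.asarray(t, dtype=float)
    T, tau = plateau_week, shoulder
    c = gain / (T - tau / 2.0)
    d = np.where(t <= T - tau, c, c * np.clip(T - t, 0.0, tau) / tau)
    return np.where(t > T, -decline_slope, d)


@dataclass(frozen=True)
class WeightlikeTruth:
    """Ground-truth metadata returned alongside a generated weight arm."""

    plateau_week: float
    gain: float
    baseline: float
    shoulder: float
    decline_slope: float

    def curve(self, t):
        return _weight_curve(
            t, self.baseline, self.gain, self.plateau_week, self.shoulder, self.decline_slope
        )

    def deriv(self, t):
        return _weight_deriv(t, self.gain, self.plateau_week, self.shoulder, self.decline_slope)


def generate_weightlike(
    N: int = 500,
    mean_gap_weeks: float = 6.0,
    t_max_weeks: float = 200.0,
    plateau_week: float = 60.0,
    decline_slope: float = 0.0,
    gain: float = 8.0,
    baseline: float = 55.0,
    shoulder: float = 8.0,
    sigma2_eps: float = 1.0,
    sigma2_b: float = 9.0,
    seed: object = None,
) -> tuple[LongitudinalDataset, WeightlikeTruth]:
    """Weight-like longitudinal arm with irregular visits.

    Each subject has a baseline visit at week 0 followed by visits at
    exponential gaps (mean ``mean_gap_weeks``), truncated at ``t_max_weeks``;
    the population curve gains ``gain`` kg at a constant rate that tapers to
    zero exactly at ``plateau_week``.  Subject intercepts and measurement
    noise are normal.  Synthetic: emulates the qualitative shape of post-
    treatment weight trajectories, not any real cohort.
    """
    if not plateau_week < t_max_weeks:
        raise ValueError("plateau_week must precede t_max_weeks")
    rng = np.random.default_rng(seed)
    truth = WeightlikeTruth(plateau_week, gain, baseline, shoulder, decline_slope)
    subs, times = [], []
    # visits per subject: enough exponential gaps to cover t_max
    n_draw = int(np.ceil(3 * t_max_weeks / mean_gap_weeks)) + 10
    for i in range(N):
        gaps = rng.exponential(mean_gap_weeks, n_draw)
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        t = t[t <= t_max_weeks]
        subs.append(np.full(len(t), i))
        times.append(t)
    subject = np.concatenate(subs)
    time = np.concatenate(times)
    b = rng.normal(0.0, np.sqrt(sigma2_b), N)
    y = truth.curve(time) + b[subject] + rng.normal(0.0, np.sqrt(sigma2_eps), len(time))
    return (
        LongitudinalDataset(subject=subject, time=time, value=y),
        truth,
    )


# ---------------------------------------------------------------------------
# replicate comparison runner
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Aggregated feature-detection proportions and plateau-time samples."""

    proportions: pd.DataFrame  # design, sigma2_eps, sigma2_b, method, threshold, proportion
    plateaus: pd.DataFrame  # design, method, rep, t_stop
    reps: int
    n_failed: int = 0


_METHOD_ORDER = ("ll", "ss", "ps")


def run_comparison(
    designs,
    reps: int = 50,
    methods=("ll", "ss", "ps"),
    n_levels: int = 100,
    r: int = 101,
    n_sim: int = 1000,
    seed: object = 0,
    alpha: float = 0.05,
    feature_thresholds=(4, 5),
) -> ComparisonResult:
    """Generate ``reps`` replicates per design, build the requested SiZer
    maps on a shared EDF grid, and tabulate feature-detection proportions
    (and plateau times for the rise-then-plateau design).

    All three maps share one ladder of effective degrees of freedom (evenly
    spaced from 2.5 up to 98% of the attainable maximum), so they scan the
    same complexities; each family's smoothing value is root-found to match
    each EDF level.  Plateau times are summarized per replicate by the median
    over levels with a detected plateau (the boxplot summary); for the
    penalized-spline map the plateau at the REML-optimal level is recorded
    separately under method ``ps_reml`` (the durability read-out used in
    data analysis).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    designs = list(designs)
    methods = tuple(methods)
    from .maps import _as_seedseq

    master = _as_seedseq(seed)
    rows, plat_rows = [], []
    n_failed = 0
    design_seeds = master.spawn(len(designs))
    for design, dss in zip(designs, design_seeds):
        rep_seeds = dss.spawn(reps)
        counts = {(m, k): 0 for m in methods for k in feature_thresholds}
        for rep, rss in enumerate(rep_seeds):
            data_seed, ps_seed, ll_seed, ss_seed, band_seed = rss.spawn(5)
            data = generate(design, seed=data_seed)
            try:
                ps_map, reml_fit = build_map(
                    data,
                    design.spec,
                    alpha=alpha,
                    n_levels=n_levels,
                    r=r,
                    n_sim=n_sim,
                    seed=ps_seed,
                    ladder="edf",
                    return_reml_fit=True,
                )
            except Exception:
                logger.warning("replicate %d of %s failed", rep, design.design_id, exc_info=True)
                n_failed += 1
                continue
            edf_grid = ps_map.edf_per_level[np.isfinite(ps_map.edf_per_level)]
            maps: dict[str, SiZerMap] = {}
            if "ps" in methods:
                maps["ps"] = ps_map
            if "ll" in methods:
                maps["ll"] = baseline_map(
                    data.time, data.value, "ll", edf_grid,
                    alpha=alpha, r=r, n_sim=n_sim, seed=ll_seed,
                )
            if "ss" in methods:
                maps["ss"] = baseline_map(
                    data.time, data.value, "ss", edf_grid,
                    alpha=alpha, r=r, n_sim=n_sim, seed=ss_seed,
                )
            for m, map_ in maps.items():
                nfeat = feature_summary(map_).map_features
                for k in feature_thresholds:
                    counts[(m, k)] += int(nfeat >= k)
            if design.design_id == "study2":
                for m, map_ in maps.items():
                    ts = [
                        _plateau_from_codes(row, map_.x_grid, np.nan).t_stop
                        for row in map_.colors
                        if row[0] != map_.MISSING
                    ]
                    ts = [v for v in ts if np.isfinite(v)]
                    t = float(np.median(ts)) if ts else np.nan
                    plat_rows.append(
                        {"design": design.design_id, "method": m, "rep": rep, "t_stop": t}
                    )
                if "ps" in methods:
                    band = derivative_band(
                        reml_fit, ps_map.x_grid, alpha=alpha,
                        n_sim=n_sim, seed=band_seed,
                    )
                    est = detect_plateau(band, lambda_used=reml_fit.lam)
                    plat_rows.append(
                        {
                            "design": design.design_id,
                            "method": "ps_reml",
                            "rep": rep,
                            "t_stop": est.t_stop if est.defined else np.nan,
                        }
                    )
        denom = reps
        for m in methods:
            for k in feature_thresholds:
                rows.append(
                    {
                        "design": design.design_id,
                        "sigma2_eps": design.sigma2_eps,
                        "sigma2_b": design.sigma2_b,
                        "method": m,
                        "threshold": k,
                        "proportion": counts[(m, k)] / denom,
                    }
                )
    return ComparisonResult(
        proportions=pd.DataFrame(rows),
        plateaus=pd.DataFrame(plat_rows, columns=["design", "method", "rep", "t_stop"]),
        reps=reps,
        n_failed=n_failed,
    )
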