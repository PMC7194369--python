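"""SiZer map assembly: color matrices over (smoothing level x time),
feature counting, plateau detection and rendering.

A SiZer map stacks derivative sign classifications over a ladder of smoothing
levels.  For the penalized-spline variant the ladder is a logarithmic grid of
the smoothing parameter lambda spanning two orders of magnitude either side
of the REML estimate; each row is an independent fixed-lambda refit with its
own simultaneous derivative band.  A "feature" is a change of the curve from
significantly increasing to significantly decreasing or vice versa; the
"durability" (plateau time) is the first time at which a significant-increase
run ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bands import DerivativeBand, derivative_band
from .basis import SplineSpec
from .mixed import FitResult, LongitudinalDataset, _Workspace

logger = logging.getLogger(__name__)

__all__ = [
    "SiZerMap",
    "FeatureSummary",
    "DurabilityEstimate",
    "lambda_grid",
    "build_map",
    "count_features",
    "feature_summary",
    "detect_plateau",
    "durability",
    "render_map",
]


@dataclass
class SiZerMap:
    """Color matrix over (smoothing level x time).

    colors[i, j] is the sign code of the derivative band at smoothing level i
    and grid time j: +1 increase (blue), -1 decrease (red), 0 indeterminate
    (purple).  Rows with a failed fit are filled with the sentinel -128.
    """

    lambda_grid: np.ndarray
    edf_per_level: np.ndarray
    x_grid: np.ndarray
    colors: np.ndarray
    alpha: float
    seed: object
    lambda_reml: float | None = None
    method: str = "ps"
    quantiles: np.ndarray | None = None

    MISSING: int = field(default=-128, repr=False)

    @property
    def n_levels(self) -> int:
        return len(self.lambda_grid)

    def to_frame(self):
        import pandas as pd

        lev, xs = np.meshgrid(np.arange(self.n_levels), self.x_grid, indexing="ij")
        return pd.DataFrame(
            {
                "level": lev.ravel(),
                "lambda": np.repeat(self.lambda_grid, len(self.x_grid)),
                "edf": np.repeat(self.edf_per_level, len(self.x_grid)),
                "x": xs.ravel(),
                "code": self.colors.ravel(),
            }
        )


@dataclass(frozen=True)
class FeatureSummary:
    """Per-level and map-wide feature counts."""

    per_level_features: np.ndarray
    map_features: int

    def detects(self, k: int) -> bool:
        """Whether the map flags at least k features at some smoothing level."""
        return self.map_features >= k


@dataclass(frozen=True)
class DurabilityEstimate:
    """First time the simultaneous CI of g' includes zero after an initial
    significant-increase run (the plateau / durability time)."""

    t_stop: float
    lambda_used: float
    defined: bool


def lambda_grid(lambda_reml: float, n_levels: int = 100, span_decades: float = 2.0) -> np.ndarray:
    """Log-even grid of smoothing parameters spanning
    [10^(log10 lambda_reml - span), 10^(log10 lambda_reml + span)],
    inclusive of both endpoints."""
    if not lambda_reml > 0:
        raise ValueError("lambda_reml must be positive")
    c = np.log10(lambda_reml)
    return 10.0 ** np.linspace(c - span_decades, c + span_decades, n_levels)


def count_features(row_codes: np.ndarray) -> int:
    """Number of sign changes among the significant runs of a code row:
    compress to the sequence of nonzero runs and return runs - 1 (or 0)."""
    codes = np.asarray(row_codes)
    sig = codes[(codes == 1) | (codes == -1)]
    if len(sig) == 0:
        return 0
    changes = int(np.sum(sig[1:] != sig[:-1]))
    return changes


def feature_summary(map_: SiZerMap) -> FeatureSummary:
    per_level = np.array(
        [
            count_features(row) if row[0] != map_.MISSING else 0
            for row in map_.colors
        ]
    )
    return FeatureSummary(per_level_features=per_level, map_features=int(per_level.max()))


def detect_plateau(band: DerivativeBand, lambda_used: float | None = None) -> DurabilityEstimate:
    """Scan codes left to right for the first point where a significant
    increase (+1) gives way to a non-increase; undefined if no +1 run exists
    or the run never ends."""
    return _plateau_from_codes(band.codes, band.x_grid, lambda_used or np.nan)


def _plateau_from_codes(codes: np.ndarray, x_grid: np.ndarray, lambda_used: float) -> DurabilityEstimate:
    codes = np.asarray(codes)
    pos = np.flatnonzero(codes == 1)
    if len(pos) == 0:
        return DurabilityEstimate(t_stop=np.nan, lambda_used=lambda_used, defined=False)
    first = pos[0]
    after = np.flatnonzero(codes[first:] != 1)
    if len(after) == 0:
        return DurabilityEstimate(t_stop=np.nan, lambda_used=lambda_used, defined=False)
    stop = first + after[0]
    return DurabilityEstimate(
        t_stop=float(x_grid[stop]), lambda_used=lambda_used, defined=True
    )


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed if seed is not None else 0)


def _default_grid(data: LongitudinalDataset, r: int) -> np.ndarray:
    lo, hi = data.time_range
    return np.linspace(lo, hi, r)


def _spec_for(data: LongitudinalDataset, spec: SplineSpec | None) -> SplineSpec:
    if spec is not None:
        return spec
    lo, hi = data.time_range
    return SplineSpec(domain_lo=lo, domain_hi=hi)


def build_map(
    data: LongitudinalDataset,
    spec: SplineSpec | None = None,
    alpha: float = 0.05,
    n_levels: int = 100,
    r: int = 101,
    n_sim: int = 10_000,
    seed: object = None,
    span_decades: float = 2.0,
    ladder: str = "lambda",
    edf_range: tuple[float, float] | None = None,
    return_reml_fit: bool = False,
) -> SiZerMap | tuple[SiZerMap, FitResult]:
    """Assemble a PS-SiZer map: one fixed-lambda refit plus derivative band
    per smoothing level.

    ``ladder='lambda'`` (the default, used for data analysis) spans
    ``span_decades`` orders of magnitude either side of the REML smoothing
    parameter.  ``ladder='edf'`` places levels at evenly spaced effective
    degrees of freedom instead -- the scale on which different smoother
    families are compared -- spanning ``edf_range`` (default: 2.5 up to 98%
    of the attainable maximum).

    Per-level quantile simulations use independent child seeds spawned from
    the master seed, so the map is deterministic given (data, seed).
    """
    spec = _spec_for(data, spec)
    ws = _Workspace(data, spec)
    reml_fit = ws.fit_reml()
    if ladder == "lambda":
        lams = lambda_grid(reml_fit.lam, n_levels, span_decades)
    elif ladder == "edf":
        gamma_b = reml_fit.vc.sigma2_b / reml_fit.vc.sigma2_eps
        if edf_range is None:
            edf_fn = ws.edf_function(gamma_b)
            scale = np.trace(ws.TtT) / (ws.M - ws.d)
            edf_range = (2.5, 0.98 * edf_fn(scale * 1e-10))
        targets = np.linspace(edf_range[0], edf_range[1], n_levels)
        lams = np.array([ws.lambda_for_edf(e, gamma_b) for e in targets])[::-1]
    else:
        raise ValueError(f"unknown ladder {ladder!r}")
    x_grid = _default_grid(data, r)
    children = _as_seedseq(seed).spawn(n_levels)
    colors = np.full((n_levels, r), SiZerMap.MISSING, dtype=np.int16)
    edfs = np.full(n_levels, np.nan)
    qs = np.full(n_levels, np.nan)
    for i, lam in enumerate(lams):
        try:
            fit = ws.fit_fixed_lambda(lam)
            band = derivative_band(fit, x_grid, alpha=alpha, n_sim=n_sim, seed=children[i])
        except Exception:  # pragma: no cover - defensive per-level guard
            logger.warning("fit failed at level %d (lambda=%.3g)", i, lam, exc_info=True)
            continue
        colors[i] = band.codes
        edfs[i] = fit.edf
        qs[i] = band.q
    map_ = SiZerMap(
        lambda_grid=lams,
        edf_per_level=edfs,
        x_grid=x_grid,
        colors=colors,
        alpha=alpha,
        seed=seed,
        lambda_reml=reml_fit.lam,
        method="ps",
        quantiles=qs,
    )
    if return_reml_fit:
        return map_, reml_fit
    return map_


def durability(
    data: LongitudinalDataset,
    spec: SplineSpec | None = None,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    r: int = 101,
    seed: object = None,
) -> DurabilityEstimate:
    """Plateau time at the optimum (REML) smoothing level: the first time the
    simultaneous (1 - alpha) CI of g' includes zero after an initial
    significant increase."""
    spec = _spec_for(data, spec)
    fit = _Workspace(data, spec).fit_reml()
    band = derivative_band(fit, _default_grid(data, r), alpha=alpha, n_sim=n_sim, seed=seed)
    return detect_plateau(band, lambda_used=fit.lam)


_SIZER_COLORS = {  # code -> display color
    -1: "#d62728",  # red: significant decrease
    0: "#9b59b6",  # purple: indeterminate
    1: "#1f77b4",  # blue: significant increase
}
_SIZER_COLORS_GRAYSCALE = {-1: "#252525", 0: "#969696", 1: "#f0f0f0"}


def render_map(map_: SiZerMap, path: str, grayscale: bool = False) -> None:
    """Render a SiZer map as a PNG heatmap: x = time, y = smoothing level
    (annotated with EDF), blue/purple/red cells and a legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.patches import Patch

    palette = _SIZER_COLORS_GRAYSCALE if grayscale else _SIZER_COLORS
    cmap = ListedColormap([palette[-1], palette[0], palette[1]], name="sizer")
    cmap.set_bad("#ffffff")
    norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)
    shown = np.ma.masked_where(map_.colors == map_.MISSING, map_.colors.astype(float))

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.pcolormesh(
        map_.x_grid,
        np.arange(map_.n_levels),
        shown,
        cmap=cmap,
        norm=norm,
        shading="nearest",
    )
    ax.set_xlabel("time")
    ax.set_ylabel("smoothing level (EDF)")
    ticks = np.linspace(0, map_.n_levels - 1, min(6, map_.n_levels)).astype(int)
    ax.set_yticks(ticks)
    ax.set_yticklabels(
        [f"{map_.edf_per_level[i]:.1f}" if np.isfinite(map_.edf_per_level[i]) else "-" for i in ticks]
    )
    ax.legend(
        handles=[
            Patch(color=palette[1], label="increase"),
            Patch(color=palette[0], label="no change"),
            Patch(color=palette[-1], label="decrease"),
        ],
        loc="upper right",
        fontsize=8,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
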