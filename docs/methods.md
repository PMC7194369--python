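# Methods

## The model

`pssizer` estimates where a longitudinal biomarker trajectory is
significantly increasing, decreasing, or flat, across a whole ladder of
smoothing levels at once.  Measurements y_ij on subject i at time x_ij are
modeled as

    y_ij = g(x_ij) + b_i + eps_ij,
    b_i ~ N(0, sigma_b^2),   eps_ij ~ N(0, sigma_eps^2),

where g is a smooth population curve and b_i a subject random intercept that
absorbs the within-subject correlation of repeated measurements.  g is a
P-spline: a rich cubic B-spline basis on evenly spaced knots with a
second-order difference penalty lambda * a' D_2' D_2 a on the coefficients.
Eigendecomposing D_2' D_2 splits the coefficients into an unpenalized linear
part (the penalty nullspace, X beta) and a penalized part (Z_B u with
u ~ N(0, sigma_u^2 I)), turning the penalized fit into a linear mixed model
in which lambda = sigma_eps^2 / sigma_u^2.  All three variance components are
estimated by REML; b and u are EBLUPs.

Numerically, the REML criterion is profiled over sigma_eps^2 in closed form
and optimized over the two log variance ratios with L-BFGS-B from three
starting points.  Each criterion evaluation is a Cholesky factorization of
the joint penalized normal equations, of size (M + N) where M is the basis
size and N the number of subjects, assembled from cross-products computed
once per dataset; the cost of a refit is therefore independent of the number
of records, which is what makes maps with a hundred levels (and replicated
simulation studies) cheap.  The marginal covariance
V = sigma_b^2 ZZ' + sigma_eps^2 I is never formed densely — its inverse is
applied through the one-rank-per-subject Woodbury identity.

The coefficient covariance of the smooth term Phi = (beta, u) is
Sigma = (C' V^-1 C + D)^-1 with C = [X, Z_B] and
D = blockdiag(0, I / sigma_u^2).  This is the unique scaling under which
Sigma C' V^-1 y reproduces the penalized least-squares solution and which
reduces to the standard Bayesian covariance sigma_eps^2 (C'C + lambda D_2'D_2)^-1
when sigma_b^2 = 0.  The implementation was cross-checked against an
independent dense-matrix oracle and against mgcv::gam (P-spline plus random
effect, REML), which reproduces our derivative estimates and standard errors
to three or more decimals.

## Derivative bands and the map

The curve's first derivative is g'(x) = C'_x Phi with the differentiated
basis, and se(g'(x)) = sqrt(C'_x Sigma C'_x').  Because a SiZer map tests
every grid point simultaneously, pointwise intervals are too narrow; the band
uses the Monte Carlo (1 - alpha) quantile q of

    sup_x |C'_x delta| / se(g'(x)),   delta ~ N(0, Sigma),

with the order statistic of rank ceil((1 - alpha) n_sim) of the simulated
suprema.  A grid point is coded +1 (blue) if g' - q se > 0, -1 (red) if
g' + q se < 0, and 0 (purple) otherwise.  The band treats g'_hat - g' as
mean-zero (the EBLUP convention); smoothing bias is not corrected, so
coverage statements hold for the smoothed curve at each level, exactly for
truths in the penalty nullspace.  With one grid point the construction
collapses to the Gaussian 1.96; with two independent points to 2.236.

A PS-SiZer map stacks these codes over a ladder of smoothing levels.  The
default ladder for data analysis is 100 log-even values of lambda spanning
log10(lambda_REML) +- 2.  At each level, lambda is held fixed while
sigma_b^2 and sigma_eps^2 are re-estimated by REML conditional on it (a
"freeze at global REML values" alternative would fix them once; the refit
mirrors how a fixed smoothing parameter behaves in standard GAM software).
Each level draws its quantile simulations from an independent child of the
master seed, so maps are bit-reproducible and insensitive to the number of
levels upstream.

Two summaries are read off a map or band:

* **features** — a row's number of sign alternations among its significant
  runs (zeros dropped, repeats merged, count = runs - 1); a map detects k
  features if any level's row shows at least k.  This any-level aggregation
  is deliberately the sensitive reading; it is the main knob in the
  detection proportions below.
* **durability / plateau** — scanning left to right, the first grid time at
  which an initial significant-increase run ends (the band first includes
  zero).  The `durability()` tool reads this at the REML-optimal level.

## Baselines

Two classical scatterplot-smoother SiZer engines are included; both
deliberately treat every record as independent (that is the contrast the
penalized variant addresses).

* **Local linear (LL)**: Gaussian-kernel weighted least squares of a local
  line at each grid point; the slope estimates g'.  Its variance uses the
  local weighted residual variance with a sum(w) - 2 sum(w^2)/sum(w)
  degrees-of-freedom correction, and its row quantile is the classical
  independent-blocks approximation q = Phi^-1((1 + (1-alpha)^(1/m))/2) with
  m = range/(2h) blocks (a sup-simulation switch exists).
* **Smoothing spline (SS)**: the minimizer of sum (y - g)^2 +
  lam * int g''^2, represented as a penalized cubic B-spline regression with
  knots at the unique data locations (thinned to at most 200 quantile-placed
  knots for large data), the roughness matrix computed exactly by two-point
  Gauss quadrature per interval, and the same eigenbasis reparameterization
  as the P-spline for conditioning.  Its rows use the same sup-simulation
  quantile as the penalized map.

Smoother families are compared at matched complexity: the effective degrees
of freedom (EDF), the trace of the hat matrix.  EDF is continuous and
strictly decreasing in each family's smoothing value, so matching is a
bracketed root-find (tabulated and interpolation-inverted for the
baselines), accurate to 0.1 EDF.  In the replicated comparison studies all
three maps share one ladder of EDF targets, evenly spaced from 2.5 up to
98% of the attainable maximum for the design.

## Synthetic designs

* **study1** (feature detection): f(x) = 65 + 25 e^{-2x} sin(5 pi (x+5)) on
  the closed interval [0, 1] — five derivative sign changes with
  geometrically shrinking amplitude (the fifth feature's envelope is about
  4.2 units).  N = 100 subjects, n_i = 10 shared equally spaced times,
  b_i ~ N(0, sigma_b^2), eps ~ N(0, sigma_eps^2).  The closed interval
  matters: without data beyond x = 0.892 the fifth feature is invisible to
  every smoother.
* **study2** (plateau detection): f(x) = 85 - x/4 - e^{-(x-4.5)} on the
  half-open grid x_j = 1 + 19 j / 10, whose derivative crosses zero once at
  x = 4.5 + ln 4 ≈ 5.886.  Defaults sigma_eps^2 = 10, sigma_b^2 = 5.
* **weightlike** (durability ground truth): a population weight curve rising
  at a constant rate that tapers linearly to zero over an 8-week shoulder
  ending exactly at a chosen plateau week (total gain 8 kg from a 55 kg
  baseline, optional linear decline afterwards), subject intercepts
  (sigma_b^2 = 9 kg^2), measurement noise (sigma_eps^2 = 1 kg^2), and
  irregular visits: a baseline visit plus exponential gaps with a 6-week
  mean over 200 weeks of follow-up, for 500 subjects.  The exact
  derivative-zero time is returned as metadata, which is what the durability
  tests check against.  This generator emulates the qualitative shape of
  post-treatment weight trajectories only; it has no dropout, no
  covariates, no heteroscedasticity, and its plateau is exact rather than
  asymptotic — so passing durability tests demonstrate the pipeline's
  correctness, not clinical calibration.

A per-subject random-phase variant of the study designs (`jitter=True`)
spreads visit times irregularly over the interval; it is off by default and
used only for robustness checks.

## Replicated comparison studies

`run_comparison` generates replicates, builds the three maps per replicate
on the shared EDF ladder, and tabulates (a) the proportion of replicates in
which each map detects at least 4 or 5 features (study1) and (b) each map's
plateau time (study2), summarized per replicate by the median over levels
with a detected plateau — the penalized map's plateau at its REML-optimal
level is recorded separately (`ps_reml`).  Reduced settings used by the test
suite are 20 replicates, 40 levels, 1000 quantile draws; the acceptance
script uses 50 replicates, 100 levels, 2000 draws.  2000 draws put the Monte
Carlo error of the 95% sup quantile below 2%, which is negligible against
the replicate-to-replicate spread.

**Detection saturation.**  Under these designs the feature-detection
proportions are essentially at ceiling for every smoother family: with
1,000 observations on [0, 1], even the smallest (fifth) feature has a
signal-to-noise ratio of 5-20 at the levels that resolve it, so all three
maps flag four and usually five features in nearly every replicate, and the
method ranking shows up as ties at 100% rather than as spread proportions.
The plateau-time comparison is the discriminating benchmark at this sample
size: the penalized map's pooled median lands within a few percent of the
true 5.886 while both baselines' medians land above 6 (they smear the rise
and keep the increase "significant" for longer).  The durability pipeline on
the weight-like arms recovers 60- and 134-week plateaus within one grid step
(2 weeks at the default 101-point grid over 200 weeks).

## Numerical choices and edge cases

* Knots: `n_internal_knots` evenly spaced knots strictly inside the domain
  plus boundary knots, extended degree-p knots beyond each side (uniform
  basis, uniform penalty meaning); default 23 interior knots → M = 27 cubic
  functions, large enough that lambda rather than M governs smoothness.
  Evaluation at the closed right endpoint uses the limit-from-the-left
  convention.
* Nullspace threshold for penalty eigenvalues: 1e-10 x largest eigenvalue.
* REML convergence: relative criterion change below 1e-12, projected
  gradient below 1e-7, log-ratio bounds +-25; components pinned at a bound
  are flagged (`at_bound`), not fatal — a flat truth legitimately pins
  sigma_u^2 at zero.
* Subjects with a single visit are allowed; they inform the curve with
  inflated marginal variance.  At least two subjects are required
  (sigma_b^2 is unidentifiable otherwise), and more observations than basis
  functions.
* Quantile rank: ceil((1 - alpha) n_sim) on ascending suprema; derivative
  grid default r = 101 equally spaced points over the observed time range.
* Durability on weight-like data uses a finer basis (48 interior knots over
  200 weeks, ~4-week resolution) so the detected plateau is limited by the
  evaluation grid, not by basis resolution.
* Failed per-level fits leave an all-missing map row (sentinel -128) with a
  logged warning; they are excluded from feature counts.

## Known limitations

* Bands are not bias-corrected; near sharp bends the derivative band covers
  the smoothed derivative at that level, not the true derivative.
* The subject model is an intercept only — no random slopes or serial
  correlation; misspecification there narrows the bands.
* The local-linear baseline's blocks quantile is an approximation; its
  absolute detection rates (unlike its ranking against the other methods)
  are sensitive to that choice.
* Confidence intervals for the durability time itself are not provided;
  bootstrap-over-subjects would be the natural extension.
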