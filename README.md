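# pssizer

Scale-space significance maps (SiZer — *SIgnificant ZERo crossings of
derivatives*) for longitudinal biomarker trajectories.

Clinical biomarkers measured repeatedly on the same patients — body weight
after starting therapy, CD4 counts, inflammatory markers — raise two
questions a single smoothed curve cannot answer honestly: *when does the
marker significantly rise or fall?* and *when does an initial improvement
stop (how durable is it)?*  A SiZer map answers them at every level of
smoothing simultaneously: it colors each (time, smoothing level) pixel blue
where the first derivative of the fitted curve is significantly positive,
red where significantly negative and purple where indeterminate, so real
features persist across levels while artifacts of one bandwidth do not.

Classical SiZer engines (local linear kernel regression, smoothing splines)
treat all records as independent.  With longitudinal data that is wrong:
repeated measurements on one subject are correlated, and visits are
irregular.  `pssizer` implements the penalized-spline SiZer for this
setting:

* model: y_ij = g(x_ij) + b_i + eps_ij with a subject random intercept
  b_i ~ N(0, σ_b²);
* g is a P-spline (cubic B-splines, evenly spaced knots, second-order
  difference penalty), rewritten as a linear mixed model so the smoothing
  parameter λ = σ_ε²/σ_u² is a REML-estimated variance ratio;
* simultaneous (1−α) bands for g′ via the Monte Carlo quantile of
  sup_x |C′_x δ|/se(ĝ′(x)), δ ~ N(0, Σ), Σ = (CᵀV⁻¹C + D̆)⁻¹;
* maps over 100 smoothing levels spanning log10(λ_REML) ± 2 (or a ladder of
  effective degrees of freedom for cross-method comparisons);
* the classical local-linear and smoothing-spline SiZer baselines at matched
  EDF, and replicated benchmark studies for feature and plateau detection.

Refitting at each map level costs one small Cholesky solve independent of
the number of records, so maps over data with millions of rows are feasible.

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

Detect the plateau of a rise-then-plateau biomarker (truth
f(x) = 85 − x/4 − e^{−(x−4.5)}, whose derivative crosses zero at
x = 4.5 + ln 4 ≈ 5.886), from 100 subjects with 10 visits each,
σ_ε² = 10, σ_b² = 5:

```python
import numpy as np
from pssizer import PSSiZer, SimDesign, generate
from pssizer.maps import _plateau_from_codes

data = generate(SimDesign("study2", sigma2_eps=10, sigma2_b=5), seed=7)
est = PSSiZer(n_levels=40, n_sim=2000, ladder="edf", random_state=0)
est.fit(data.time.reshape(-1, 1), data.value, groups=data.subject)

print(f"lambda_REML = {est.lambda_reml_:.3f}")
print(f"EDF at REML optimum = {est.reml_fit_.edf:.2f}")
print(f"variance components: eps^2 = {est.reml_fit_.vc.sigma2_eps:.2f}, "
      f"b^2 = {est.reml_fit_.vc.sigma2_b:.2f}")
t = [_plateau_from_codes(row, est.map_.x_grid, np.nan).t_stop
     for row in est.map_.colors]
t = [v for v in t if np.isfinite(v)]
print(f"median plateau over levels = {np.median(t):.2f}  (truth: 5.886)")
```

prints

```
lambda_REML = 1.310
EDF at REML optimum = 9.91
variance components: eps^2 = 8.94, b^2 = 3.85
median plateau over levels = 5.36  (truth: 5.886)
```

The REML fit recovers the error and subject variances (8.9 vs 10, 3.9 vs 5
— within sampling error for one replicate), and the map's pooled
blue-to-purple transition lands within half a time unit of the true plateau.
`est.map_` holds the full color matrix (`pssizer.render_map` draws it);
`est.durability_` is the plateau read at the REML-optimal level.

## Command line

```bash
pssizer simulate --design study2 --sigma-eps 10 --sigma-b 5 --seed 3 --out data.csv
pssizer map --input data.csv --levels 100 --nsim 10000 --seed 4 \
            --out map.png --export map.csv
pssizer durability --input data.csv --seed 5 --out durability.json
pssizer compare --design study1 --sigma-eps 5 --sigma-b 2 --reps 20 --seed 6 \
            --out table.csv
```

Every command writes a JSON metadata sidecar (configuration, seed, λ_REML,
EDF range, version) so runs can be replayed; identical seeds give
byte-identical outputs.

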