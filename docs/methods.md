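# Methods

## Model and estimand

A predator population observed at k time points yields diet compositions
`pi_ij` (individual i, time j) over M prey species.  Repeatability is the
two-way-model intraclass correlation

    rho = sigma_s^2 / (sigma_s^2 + theta_t + sigma_e^2),

where `sigma_s^2` is the among-individual variance, `theta_t = sum_j t_j^2/(k-1)`
collects fixed time effects, and `sigma_e^2` is residual variance.  The model
assumes no individual×time interaction (one observation per cell) and treats
time levels as fixed.  Three population quantities are distinguished:
`rho_pi` (the ICC of the *true* diets — the estimand), `rho_p` (the ICC of the
corresponding population of QFASA diet estimates), and their sample versions;
the gap between them is the measurement-error bias handled below.

## Distance-based sums of squares

Compositional responses with essential zeros rule out both classical MANOVA
and log-ratio geometry, so mean squares come from a distance-based ANOVA:

* **CS distance.**  `CS(p1,p2) = sqrt(c_M * sum_m r_m)` with
  `r_m = (q1m-q2m)^2/(q1m+q2m)` on the sum-normalized vectors and `r_m = 0`
  when both components are exactly zero.  The zero test is exact equality
  (proportions are read from files, not computed residuals), inputs are
  always renormalized first (percent and proportion encodings behave
  identically), and there is **no** column standardization across
  observations (this is not the correspondence-analysis chi-square
  distance).  The constant is taken as `c_M = 2/M`; the estimator is
  invariant to it (verified to 1e-12 in the tests), so the choice affects
  raw distances only.
* **Gower centering and sequential projections.**  With `A = -0.5 D∘D` and
  `C = I - 11'/N`, `G = CAC`; the SS of nested designs (intercept ⊂
  intercept+predator ⊂ intercept+predator+time) are trace differences
  `tr((H_{l} - H_{l-1}) G)` with hat matrices from SVD-orthonormalized dummy
  expansions, so rank deficiency from missing cells cannot crash the fit.
  This trace route is used rather than group-sum formulas because the
  sequential unbalanced case has no closed group-sum form; on balanced
  layouts it agrees with the Huygens pairwise-sum shortcut (tested), and on
  univariate Euclidean data it reproduces classical sequential least-squares
  ANOVA to 1e-10 (tested, including against vegan's `adonis2`).
  The predator factor is entered first by default (order is configurable);
  order matters only for unbalanced layouts.  Permutation p-values are
  deliberately out of scope — they are not needed for rho.

## Point estimators

Balanced: `rho_hat = (MS_s - MS_e)/(MS_s + (k-1)MS_e + (k/n)(MS_t - MS_e))`,
the two-way mixed-model absolute-agreement ICC (cross-checked against
pingouin's ICC(A,1) on univariate data).  Unbalanced: the harmonic mean
`k_tilde = n/sum(1/k_i)` replaces k, with df `(n-1, k_tilde-1,
sum(k_i)-1-df_s-df_t)`; the residual df is parsed as total-minus-others
because only that parse reduces to `(n-1)(k-1)` when balanced (and the
unbalanced estimator then coincides exactly with the balanced one — tested).
The time factor's *design* df (its actual number of levels) is used for the
sequential SS; the `k_tilde`-based df governs the mean squares.  Estimates
are reported unclamped; negative values are legitimate and clamping would
bias the bootstrap distributions built on top.

## QFASA estimation

Predator signatures are calibrated by dividing by per-FA calibration
coefficients and renormalizing (the division convention of the original
formulation; zeros stay zero).  The diet solves
`min_alpha dist(q, A alpha)` over the simplex, where A's columns are
species-mean prey signatures floored at 1e-6 and renormalized; the default
objective is the symmetric KL-type divergence `sum (q-m) log(q/m)`, with
squared-CS and clr-Euclidean alternatives.  All three are convex in the
mixture `m = A alpha` (hence in alpha), so the SLSQP solves with analytic
gradients are reliable; the default still uses 5 seeded Dirichlet restarts
as insurance, while the simulation loops use a single uniform start (a
problem-size choice justified by convexity; recovery of 200 random noiseless
mixtures is exact to <1e-3 either way).  FA-space weights are converted to
diet proportions by fat weighting `pi_s ∝ alpha_s / fat_s`.  FA-subset
selection is the caller's responsibility via the library reader.

## Pseudo-predators

A pseudo-predator signature for true diet pi: FA-space weights
`w_s ∝ pi_s * fat_s` (the exact inverse of the fat weighting above, so the
generate→estimate round trip is centered on pi — verified by Monte Carlo to
±0.03 per species over 500 draws); integer draw counts by largest-remainder
rounding of `w * draws_per_predator` (deterministic, sums exactly, any
species with ≥0.5 expected draws gets ≥1); individuals sampled with
replacement within species and averaged with weights w; then mapped to
predator space by multiplying by the calibration coefficients and
renormalizing.  `draws_per_predator` defaults to 30 — the sampling intensity
is not pinned down by the method description, so it is an explicit,
logged configuration choice.  Several published pseudo-predator variants
exist; only this one is implemented.

## Nested bootstrap confidence intervals

For b = 1..B: regenerate the entire panel as pseudo-predators (true diet :=
observed estimate) and re-estimate diets, giving `rho*_b`; for r = 1..R:
resample predators with replacement (each carrying all its diets and
missingness — the cluster bootstrap), giving `rho**_{br}`.  All B×R
replicates are pooled into one empirical distribution.

* **Studentized T:** pivots `z_{br} = (rho**_{br} - rho*_b)/sqrt(v_{br})`,
  interval `(rho_hat - sqrt(v_orig) q_{1-a/2}(z), rho_hat - sqrt(v_orig) q_{a/2}(z))`
  with type-7 quantiles.  Variances are delete-one-predator jackknifes; by
  default `v_{br}` is computed inside each resample (self-studentizing —
  the nesting of the jackknife is not specified by the method description,
  so this is a design choice, with a cheaper per-b variant behind a flag).
  Pivots are centered on their own block's `rho*_b`.
* **BCa:** bias factor z0 from the pooled fraction of replicates below
  `rho_hat`, acceleration from jackknife skewness on the original panel,
  standard percentile mapping; falls back to the plain percentile interval
  with a warning if all replicates fall on one side.
* **Bias correction:** `d_hat = mean_b(rho*_b) - rho_hat` estimates the
  pseudo-to-sample bias; assuming it equals the sample-to-truth bias, the
  point estimate shifts by `d_hat` and interval endpoints by `2 d_hat`.
  `d_hat` is negative in practice (noisy diet estimates attenuate rho) and
  grows in magnitude with rho (tested).
* Failed fits (degenerate resamples) are dropped and counted; >5% failures
  aborts.  Reported endpoints are truncated to [0,1] by default (the
  estimand lives there); untruncated values are kept in the result.
  Identical seeds give identical reports (tested).

## Simulated populations and coverage

Population grids are built in ilr space (scikit-bio's fixed orthonormal
basis): `cell(i,j) = ilr(mu) + row_i + col_j + eps_ij`, rows ~ MVN(0,
diag(v)), `col_j = ±c·ilr(mu)` for k=2 (equally spaced zero-sum multiples
for k>2 — an extension beyond the described k=2 recipe), eps ~ N(0,
sigma_e^2 I).  Column effects are applied in ilr space — "a constant times
the mean diet vector" is ambiguous between simplex and transform space, and
the ilr choice keeps every cell a valid strictly positive composition.
Zero-mean species are pruned from the base diet before the transform.  The
grid's true rho is the balanced estimator on all N×k cells (O(N²) Huygens
shortcut).  `calibrate_column_constant` bisects on c (rho is monotone
decreasing in it) to hit a target rho within 0.01; targets above the c=0
ceiling require larger row variances and error out rather than silently
recalibrating.  A helper derives base diet, row variances (empirical ilr
variances, zeros floored at 1e-6) and residual SD (0.25 × median row SD)
from a panel of real diet estimates.

Coverage experiments sample n grid rows per simulation, observe them through
the pseudo-predator + QFASA process, run the full CI machinery, and report
the fraction of shifted intervals containing the grid's true rho with the
binomial margin of error `1.96 sqrt(p(1-p)/nsim)`.

## Synthetic data generator

`generate_fixture` emulates the structure of real QFASA inputs: a prey
library of 6 species × 12 FAs × 20 individuals whose species means are
redrawn until every pair is separated by CS distance > 0.2 (separable prey,
as in a curated library), logistic-normal within-species variation (SD 0.25
in log space), lognormal calibration coefficients near 1, fat contents
uniform on 2–12%, and panels sampled from ilr grids with known true
repeatability (row variance 1, residual SD 0.25, column constant 0.5 —
mid-to-high repeatability, the regime the method targets).  It does *not*
emulate: correlated FA measurement noise, prey substructure/clustering,
non-separable species, FA subsets with exclusions, or diet estimates whose
zeros reflect detection limits.  Passing tests therefore demonstrate
correctness of the machinery and qualitative behavior (attenuation,
coverage, bias growth), not performance on any particular real predator
system.

## Problem sizes

The default test-suite and acceptance-script runs are scaled down relative
to a production analysis: grids of 200–1000 rows (vs. 1000), B×R from 4×30
up to 50×100 (a production run uses 50–100 × 100), 10–40 simulations per
coverage experiment (vs. 100), and single-start solves inside loops.  These
sizes are stated in each script; the package's defaults (`B=100`, `R=100`,
5 restarts) reflect production use.

## Known limitations

* The bias correction assumes the pseudo-to-sample and sample-to-truth
  biases are equal; when true repeatability is very high (≈0.95) the
  correction under-covers.
* The measurement-error component of the CI machinery is specific to
  QFASA-style estimation (it needs a generative model for signatures);
  sampling-error-only CIs apply to other compositional diet estimators.
* One-way (no time effect) repeatability, >2 factors, interactions, and
  permutation tests are out of scope.
* Grid column effects beyond k=2 use an invented equally-spaced scheme.
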