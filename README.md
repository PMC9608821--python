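# comprep — repeatability of compositional diet estimates

`comprep` measures the *repeatability* (intraclass correlation, ICC) of
predator diets that come as compositional vectors — proportions over M prey
species summing to 1, typically with many exact zeros because not every
predator eats every species.  Such estimates arise from quantitative fatty
acid signature analysis (QFASA), stomach or fecal contents, or stable
isotopes.  The package is for ecologists and biostatisticians who have
repeated diet estimates per individual and want to know how much of the total
diet variation is attributable to consistent differences among individuals,
with honest uncertainty that accounts for the fact that the diets themselves
are estimated.

## The statistic

For a two-way (individual × time) layout, repeatability is

    rho = sigma_s^2 / (sigma_s^2 + theta_t + sigma_e^2),

the among-individual share of total variance, with `theta_t = sum_j t_j^2/(k-1)`
summarizing fixed time effects.  With n individuals and k repeated diet
vectors each, the estimator plugs in mean squares from a *distance-based*
two-way ANOVA (the PERMANOVA trace construction: Gower-centered squared
distances, sequential projections, predator entered first):

    rho_hat = (MS_s - MS_e) / (MS_s + (k-1) MS_e + (k/n)(MS_t - MS_e)).

Distances are chi-square (CS) distances,
`CS(p1,p2) = sqrt((2/M) * sum_m (q1m - q2m)^2 / (q1m + q2m))` (both-zero
components contribute 0), which tolerate essential zeros — unlike log-ratio
(Aitchison) distances.  `rho_hat` is provably invariant to the leading
constant of the distance.  Unbalanced designs (unequal counts k_i) use the
harmonic mean `k_tilde = n / sum_i (1/k_i)` and modified degrees of freedom
`df_s = n-1`, `df_t = k_tilde-1`, `df_e = (sum k_i) - 1 - df_s - df_t`.

Because QFASA diets are *estimates*, `rho_hat` is attenuated by measurement
error.  Confidence intervals therefore nest two loops: B outer replicates
regenerate the panel as *pseudo-predators* (FA signatures resampled from the
prey library under the observed diets) and re-estimate their diets with
QFASA; R inner replicates resample predators (clusters) with replacement.
Studentized-T and BCa intervals are built from the pooled B×R replicates with
delete-one-predator jackknife standard errors; the bias
`d_hat = mean_b(rho*_b) - rho_hat` shifts the point estimate by `d_hat` and
interval endpoints by `2 d_hat`.

## Worked example

```python
from comprep import estimate_repeatability, generate_fixture, repeatability_with_ci

fx = generate_fixture(seed=3)           # synthetic prey library + panels
est = estimate_repeatability(fx.panel_balanced)
print(est.rho_hat)                      # 0.6331

report = repeatability_with_ci(fx.panel_balanced, fx.library, fx.cc,
                               B=20, R=50, rng=11)
print(report.d_hat)                     # -0.0325
print(report.rho_adjusted)              # 0.6656
print(report.intervals["t"].lower_reported,
      report.intervals["t"].upper_reported)   # 0.5862 0.9414
```

The panel was sampled from a population grid whose true repeatability is
0.6322: the raw estimate (0.6331) is close, the bootstrap bias estimate is
negative (measurement error attenuates), the adjusted estimate corrects for
it, and the shifted 95% interval covers the truth.  The scripts in
`examples/` walk through each capability (point estimation, the QFASA
round trip, bootstrap CIs, coverage simulation) with printed output.

A thin CLI mirrors the library: `comprep estimate | ci | qfasa | pseudo |
simulate | fixture` (see `comprep --help`).

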