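# hac24

Three analytic lenses on the **24-hour activity cycle** (24HAC) — the
partition of each day into sitting, standing, stepping, and sleep — and its
association with a continuous health outcome:

* **Isotemporal substitution models (ISM).** Regress the outcome on all
  activity variables but one, plus the total time per day and covariates:
  `E(Y) = b0 + b1·Sit + b2·Stand + b3·Sleep + b4·Total + g'X` (step
  dropped).  With `Total` held, `b1` is the estimated change in mean outcome
  per minute moved from the *dropped* behavior into sitting — the
  substitution effect.  Linear, subgroup-stratified, and penalized-cubic-
  spline (GCV-selected) variants are provided.
* **Compositional data analysis (CoDA).** Treat the day as a composition
  `x = (sit, stand, step, sleep)`, map it to pivot isometric-log-ratio
  coordinates `z_i = sqrt((D-i)/(D-i+1)) · ln(x_(i)/gmean(x_(i+1..D)))`,
  and fit `E(Y) = b0 + b1·z1 + b2·z2 + b3·z3 + g'X`.  Coefficients translate
  into time-reallocation effect curves (one-vs-remaining and pairwise) with
  delta-method confidence bands, plus compositional descriptives (closure,
  compositional mean, variation matrix, ternary plots, James's test).
* **Latent profile analysis (LPA).** A finite mixture of multivariate
  normals over the waking behaviors (multi-start EM, AIC/BIC/CAIC/aBIC/
  ICL-BIC/entropy, bootstrap likelihood-ratio test) followed by
  distal-outcome association that corrects the bias of treating modal class
  assignments as observed: the **BCH** weighted three-step estimator
  (weights from the inverse classification-error matrix `D^-1`) and the
  step-3 **maximum-likelihood** estimator, both with robust standard errors.

A synthetic cohort generator with known ground truth (latent activity
classes, daily records near 1,440 min/day, covariate marginals, a linear
outcome model) makes every stage runnable and testable without external
data.  The package is aimed at biostatisticians and activity-epidemiology
researchers comparing these approaches or building simulation studies
around them.

## Worked example

```python
import hac24 as h

# a compositional mean of 10.23 h sit, 3.68 h stand, 1.24 h step, 8.85 h sleep
base = h.close([10.23, 3.68, 1.24, 8.85])
print([float(round(p * 100, 1)) for p in base.proportions])
# [42.6, 15.3, 5.2, 36.9]

# add 10 min/day of stepping, shrinking the other behaviors proportionally
spec, new = h.one_vs_remaining_realloc(base, "step", 10.0, day_length=1440)
print(round(spec.r * 100, 1), round(spec.s * 100, 2))
# 13.4 0.73        <- stepping rises by 13.4%; the rest each shrink by 0.73%
print(round((base.part("stand") - new.part("stand")) * 1440, 2))
# 1.62             <- standing gives up about 1.6 minutes

# end-to-end on a synthetic cohort
cfg = h.RunConfig(cohort=h.CohortConfig(n_persons=500, n_days=7, seed=1),
                  seed=1, outdir="demo_run", lpa_k_range=(2, 3, 4),
                  lpa_k_final=4)
results = h.run_all(cfg)
print(results["distal_bch"].summary().round(3))
#          estimate  robust_se  p_value
# class_0    -0.082      0.112    0.467
# class_1    -0.018      0.135    0.892
# class_2     0.000        NaN      NaN
# class_3    -0.318      0.153    0.038
```

The run writes a report bundle (`table2_ism.csv`, `table3_coda.csv`,
`table5_distal.csv`, model-selection and classification-error tables,
ternary/curve/boxplot figures, an exclusion log, and a `manifest.json`
with the seed) under `demo_run/`.  The distal summary above is
reference-coded against the largest ("average activity") profile:
profile 4, the least-active class, sits about 0.32 SD units below it on
the cognitive score.  The naive modal regression on the same run returns
−0.242 (SE 0.116) for that contrast — attenuated toward zero with a
too-small standard error, which is exactly the bias the BCH weighting
corrects.

The same pipeline is scriptable from the shell:

```bash
hac24 run-all --config run.yaml --seed 1 --out demo_run
```

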