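# Methods

This note records the statistical models implemented in `hac24`, the
assumptions behind them, the choices made where the design was open, and
what the synthetic cohort does and does not emulate.

## Data model

A *daily record* holds minutes of sitting, standing, stepping (waking
behaviors), sleep (time in bed, from a sleep log), waking wear minutes, and
the day length.  Days run out-of-bed to out-of-bed, so day lengths vary
around 1,440 minutes rather than being exactly 24 h.  A day is *valid* when
it carries at least 600 minutes (10 h) of waking wear — the boundary is
inclusive — and a person enters analysis with at least 4 valid days.
Person-level behavior values are arithmetic means of daily minutes over
valid days only; sleep is always part of the day, so the four person-level
means still add up to the mean day length.  Days with valid wear but no
sleep-log entry would lack the day boundary itself and are treated as
invalid.  Zero behavior values break every log-ratio step; the default is
to raise, and the opt-in `half_min_positive` strategy replaces a zero with
half the smallest positive observed value of that behavior and re-closes
the person's day (a deliberately simple rule — fixed-value replacement is
known to distort compositions, which is why it is not the default).

## Isotemporal substitution

The linear ISM is ordinary least squares of the outcome on the retained
activities, the total time, and covariates.  Because total time varies
across persons, an intercept and `Total` coexist; if `Total` is exactly
constant the fit refuses the redundant pair and a no-intercept variant is
used instead.  Both the classical and HC1 sandwich covariances are stored;
substitution tables default to the classical one.  The four
parameterizations (one per dropped activity) span the same column space, so
fitted values agree to machine precision and the substitution table is
exactly antisymmetric.  The table's (row *i*, column *j*) entry is the
effect of moving Δ minutes *from* behavior *i* *into* behavior *j*, i.e.
Δ times the coefficient of *j* in the model that drops *i*.

The spline ISM replaces each retained activity by a cubic B-spline on
5 equally spaced knots over its observed range (range-based, not
quantile-based — the choice is flagged in the docstring), sum-to-zero
constrained so the smooth is identifiable next to the intercept, with an
exact curvature penalty (integrated squared second derivative, Gauss
quadrature per knot interval, scaled to unit Frobenius norm so one grid
serves all smooths).  Smoothing parameters minimize GCV = n·RSS/(n − edf)²
by coordinate-wise search over a 61-point log-spaced grid 10⁻⁴…10⁶
(two sweeps).  Per-smooth Wald-type tests use the penalized (Bayesian)
coefficient covariance with rank set to the rounded effective degrees of
freedom of the smooth.

## Compositional data analysis

Closure, the compositional mean (closed vector of per-part geometric
means), the variation matrix (pairwise log-ratio variances), and pivot ilr
coordinates with normalizers √((D−i)/(D−i+1)) and natural logarithms.  The
default part ordering after the pivot keeps the canonical (sit, stand,
step, sleep) sequence.  Compositions off closure by more than 1e−10 are
re-closed with a logged warning rather than rejected.

The coordinate regression is OLS of the outcome on (z1, z2, z3) plus
covariates.  Any two pivot bases are orthonormal rotations of one another,
so fitted values, contrasts and reallocation curves are basis-invariant;
only the coordinatewise coefficients change meaning.  Reallocation effects:

* one-vs-remaining — raising the pivot part by (1 + r) and shrinking the
  rest by a common (1 − s), s = r·x1/(1 − x1) with −1 < r < (1 − x1)/x1,
  moves only z1, by Δz1 = √((D−1)/D)·ln((1+r)/(1−s)); the effect is β1·Δz1
  with CI β1·Δz1 ± z·|Δz1|·SE(β1);
* pairwise and general contrasts — Δz = z(B) − z(A), effect Δzᵀβ, variance
  ΔzᵀCov(β)Δz.

Defaults: the baseline composition is the sample compositional mean; Δ
minutes convert to r through the sample's median day length (1,440 by
default); intervals are pointwise 95% normal-quantile bands from the
classical covariance (the robust one is available by flag).  An
extrapolation guard warns when a requested composition's coordinates leave
the axis-aligned bounding box of the observed coordinates — a cheaper and
more conservative proxy than a convex hull.  Because the model is linear on
the log-ratio scale, minute-scale effects are nonlinear and asymmetric;
for reallocations that are large relative to the baseline part (30 minutes
is ~40% of a typical stepping time) the ISM and CoDA estimates genuinely
diverge even under near-null associations, so the close-agreement property
between the two models is asserted only where the relative change is small.

James's test of equal mean vectors across groups with unequal covariances
uses the second-order series correction: the statistic
J = Σ (x̄ᵢ − μ̂)ᵀWᵢ(x̄ᵢ − μ̂) with Wᵢ = nᵢSᵢ⁻¹ is referred to
x(1 + A + Bx) = J solved in closed form against χ² with p(k−1) degrees of
freedom.  A seeded permutation fallback serves small samples.

## Latent profile analysis

A finite mixture of multivariate normals with class-specific full
covariance matrices (shared and diagonal structures by option).  The
indicators must be a strict subset of the closed composition — the default
is the three waking behaviors in minutes/day, keeping the profile contrast
on the interpretable raw scale; an ilr-indicator mode is possible but
log-ratios of small parts skew heavily.  EM from multiple random starts
(centroid draws perturbed around sampled points); the best final
log-likelihood wins and the number of starts replicating it is recorded as
a multimodality diagnostic.  Convergence: relative log-likelihood change
< 1e−8 or 250 iterations; class covariances keep all eigenvalues ≥ 1e−6 by
adding the floor to the M-step covariance (exact for PSD matrices and
cheaper than an eigendecomposition).  With overlapping classes the EM often
uses the full iteration budget before meeting that tight tolerance; the
final E-step re-synchronizes the posteriors with the last parameters, and
downstream steps proceed with a logged warning.

Model selection reports AIC, BIC, CAIC (−2ℓ + p(ln n + 1)), sample-size
adjusted BIC (n replaced by (n+2)/24), ICL-BIC (BIC plus twice the total
posterior entropy), the entropy statistic E = 1 − Σᵢₖ(−p_ik ln p_ik)/(n ln K),
and the minimal class share.  The bootstrap likelihood-ratio test of K vs
K−1 draws parametric samples from the fitted (K−1)-class model and uses
p = (1 + #{LR_b ≥ LR_obs})/(reps + 1); non-convergent bootstrap fits are
redrawn with a cap.

Distal-outcome step: modal assignment (ties to the lowest index, logged)
yields the classification-error matrix D[k, s] = Σᵢ p_ik·1{aᵢ = s}/Σᵢ p_ik.
The naive analysis regresses the outcome on class dummies with HC1 SEs.
BCH expands each person into K records weighted by row aᵢ of D⁻¹ (weights
can be negative; per-person they sum to one) and solves the weighted normal
equations directly — negative weights rule out the usual sqrt-weight WLS
route — with a person-clustered sandwich covariance.  The ML variant
maximizes the step-3 likelihood Σₖ πₖ·D[k, aᵢ]·φ(yᵢ; β0 + αₖ + γᵀxᵢ, σ²)
(or, in predictor role, a multinomial model of class membership filtered
through D) by BFGS, with an empirical sandwich from per-person scores and a
finite-difference Hessian.  Classes are reported sorted by ascending mean
sitting time; label switching against a reference is resolved by minimal
total Euclidean distance between class means (Hungarian assignment).
Neither three-step estimator propagates step-1 *parameter* uncertainty —
only assignment uncertainty — which is the known limitation of this family.

## Synthetic cohort

The generator draws, per person: a latent class from the profile weights
(defaults 15.9/24.4/40.3/19.4% with the per-behavior mean(SD) hours of the
four motivating profiles); a habitual behavior vector from independent
truncated-positive normals with the class means and SDs; then per-day hours
around that habit with day-to-day SD equal to `within_person_sd_scale`
(default 1.0) times the class SD, rescaled so the four behaviors exactly
fill a day length drawn as round(N(1440, 6)) — consistent with a median of
1,440 and a tight interquartile range.  The hierarchy matters: the printed
class SDs describe *between-person* spread, so drawing days directly from
the class distribution and averaging a week would shrink the person-level
spread by √7 and make the classes far too well separated.  With the
hierarchical default, person-level class separation lands at an entropy of
roughly 0.6–0.7 for the four-profile configuration.  Covariates follow the
motivating cohort's marginals (age-group 0.419/0.411/0.170, female 0.558,
BMI N(27.1, 4.9²), education N(16.8, 2.8²), CES-D truncated-at-zero
N(3.6, 3.9²), good health 0.921, White 0.902), with independent
per-field missingness (default 3%) on BMI, CES-D and race.  The outcome is
intercept + class effect + covariate effects + N(0, σ²) noise; defaults are
intercept 0.61, residual SD 0.69, and class effects (−0.048, 0.018, 0,
−0.239) relative to the average-activity class.  Seeding is one master
seed with deterministic per-person substreams, so outputs are byte-stable.

What the generator does **not** emulate: within-class correlations between
behaviors (draws are independent before closure; real sitting and standing
trade off within persons), non-normal behavior distributions, weekday/
weekend structure, wear-time artifacts, and covariates that are genuinely
associated with class membership (effects default to zero and must be
configured).  Passing tests therefore demonstrate correctness of the
estimators under the stated generating model, not robustness to the
messier features of observed accelerometry.  Closure to the day length
also shrinks the marginal SDs of the large parts relative to the
generation-scale inputs, so person-level summaries sit slightly below the
configured SDs.

## Simulation sizes used by the test suite

Calibration and recovery checks run at sizes chosen to give informative
Monte-Carlo error on a single CPU: type-I error of the ISM substitution
test over 1,000 null cohorts of n = 300 persons × 1 day (day-level
replication is irrelevant under the null); James-test null rejection over
1,000 replicates; bootstrap-LRT uniformity over 500 simulations × 99
bootstrap draws at n = 100 with a reduced EM budget (two kmeans++ starts,
60 iterations, looser tolerance — applied identically to observed and
bootstrap fits, so the comparison stays symmetric); and the naive-vs-BCH/ML bias
study over 200 cohorts of n = 1,000 at the default four-profile
conditions.  The pipeline's end-to-end run at n = 1,000 with all methods
and K ∈ {2..5} completes in minutes.

## Known limitations

* GCV smoothing-parameter search is a coordinate-wise grid, not a full
  (RE)ML optimization; very wiggly truths may prefer a finer grid.
* The James p-value uses the closed-form second-order inversion; for
  n barely above the dimension the permutation fallback is preferable.
* BCH can produce negative expanded weights by construction; with very
  poorly separated classes D becomes ill-conditioned and the estimator
  refuses (condition number > 1e6) rather than returning unstable numbers.
* The bootstrap LRT p-value has resolution 1/(reps + 1).
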