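# Methods

## Generative models

Both simulators produce a cohort of n individuals with two continuous
predictors and a binary outcome at a 20% target prevalence.

**Approach 1** draws (x₁, x₂) for the whole population from a bivariate
Gaussian N(μ, Σ) with Σ built from SDs σ = (σ₁, σ₂) and Pearson
correlation ρ (sampling via the Cholesky factor applied to independent
standard normals — deterministic given the seed). The logistic slopes
are fixed as β = log(adjusted OR); the intercept β₀ is then the unique
root of

    mean over the realized sample of expit(β₀ + β₁x₁ + β₂x₂) = prevalence,

found by Brent's method on an auto-expanded bracket around
logit(prevalence). Calibration is performed on the *realized* sample,
not the theoretical integral, so the mean predicted risk in the
simulated data hits the target to 1e-8 exactly; outcomes are then
independent Bernoulli draws from the individual risks, which makes the
realized case count binomial around n·prevalence (the realized
prevalence is stored in the cohort metadata).

**Approach 2** specifies the predictor distribution conditional on
outcome: exactly round(n·prevalence) cases from N(μ_case, Σ_case) and
the remaining controls from N(μ_control, Σ_control), concatenated and
then shuffled by a seed-derived permutation so downstream code cannot
exploit block ordering. The exact (non-random) case count is a
deliberate asymmetry versus approach 1's Bernoulli mechanism: the two
constructions are different study designs, not two implementations of
one design. Adjusted effects are emergent here and are estimated by the
logistic fit.

For approach 2 the whole-population parameters follow in closed form
from the two-component mixture (case fraction π):

    μ_t  = π μ_c + (1−π) μ_ct
    σ_t² = π σ_c² + (1−π) σ_ct² + π(1−π)(μ_c − μ_ct)²
    cov_t = π ρ_c σ₁cσ₂c + (1−π) ρ_ct σ₁ctσ₂ct + π(1−π)(μ₁c−μ₁ct)(μ₂c−μ₂ct)

and, for a predictor with common within-group SD, the unadjusted odds
ratio is exp((μ_case − μ_control)/SD²). When the group SDs differ the
formula's premise fails; the implementation then uses the control-group
SD and emits a `CommonVarianceWarning` rather than silently reporting a
number outside the formula's domain.

## Model fitting and transport

`fit_logistic` computes the two-predictor maximum-likelihood logistic
fit by Newton iterations (via `statsmodels.Logit`, method "newton"),
then verifies the optimum independently: the fit is accepted only if the
mean score vector (mean residual and mean xⱼ-weighted residual) vanishes
below 1e-8. Quasi-separation is escalated to a `SeparationError`, as is
any coefficient exceeding 50 in absolute value during fitting; a cohort
missing an outcome class or with perfectly collinear predictors is
rejected up front. Fit metadata (iterations, convergence, score norm)
travels with the model, and models round-trip through JSON at full
double precision.

Transport means applying the development coefficients unchanged in the
validation cohort — no recalibration and no refitting. Since the AUC is
rank-based, a transported AUC depends only on the *direction* of the
coefficient vector: scaling it by any positive constant changes nothing,
which is why models fitted under proportional true effects validate
identically.

## Measures

The AUC uses the midrank Mann–Whitney estimator
(ΣR_case − n₁(n₁+1)/2)/(n₁n₀) with ties counting ½ — identical to the
brute-force pairwise concordance count, which the tests verify exactly
for n ≤ 200. Development evaluations use the fixed direction (in-sample
ML fits are concordant by construction). External validations default
to auto-orientation, reporting max(A, 1−A) with a boolean flag: a
transported model whose effects point against the validation
population's truth produces a score that ranks inversely, and the
published validation matrices behave as if such entries were flipped
(e.g. the strong-effects model validated in the inverse-effects
population reports ≈0.59, not ≈0.41). Surfacing the flag keeps the
choice auditable per entry rather than baked in.

SD of the linear predictor uses the n−1 denominator (declared for
exactness in small tests; negligible at n = 10⁵). For approach-1
populations it has the closed form
√(β₁²σ₁² + β₂²σ₂² + 2ρβ₁β₂σ₁σ₂), used throughout as a moment oracle.
Outcome-group summaries (means, SDs, Pearson correlation per group)
require at least 3 members per group, below which a correlation is
degenerate.

## Experiment drivers and seeds

`develop_all` simulates, fits and evaluates one cohort per population
under a single master seed; `cross_validate` fills the full
validated-in × developed-in AUC matrix using those same realizations
(one dataset per population, matching the single-dataset-per-population
design). Validation rows index the validating population, columns the
developing one.

Every public operation takes one integer seed. Stages split their
streams by `numpy.random.SeedSequence` spawning (predictor draw vs
outcome draw vs shuffle), so changing one stage's logic cannot shift
another's stream; per-population seeds derive deterministically from
(master seed, approach, population id) and are reduced below 2³¹.
Identical spec + seed reproduces a cohort bit-for-bit.

Correlation sweeps simulate each grid point independently (fresh draws
per ρ), so curves carry Monte-Carlo jitter; monotonicity checks
therefore use a ±0.005-per-step tolerance instead of strict
inequalities. Default grids: total-population sweeps cover
ρ ∈ [−0.4, 0.4] in steps of 0.1 (correlations below 0.4 are what
non-genetic biomedical predictors typically show); outcome-conditional
sweeps accept arbitrary grids up to ±0.95, where the
equal-correlation limit ρ → +1 drives the AUC toward 1. The four
standard conditional-sweep scenarios (a–d) vary the case means and the
shared group SDs around the reference layout μ_case = (1, 2),
μ_control = (0, 0), SDs 2.

## Defaults and problem sizes

n defaults to 100,000 per population with 20% prevalence — large enough
that the AUC's standard error is ≈0.002, so reproduction checks at
±0.01 are comfortably Monte-Carlo-stable — and is configurable
everywhere for fast exploration; the bundled population sets encode the
standard 16 + 9 scenario grid at full size. The test suite develops the
full grids at n = 100,000 once per session and reuses them across
tests; examples run reduced sizes where full size adds nothing.

## What the generator does and does not emulate

Predictors are exactly Gaussian, measured without error or missingness,
with purely linear effects and no interactions; outcomes carry no
severity spectrum, and prevalence is never varied (the AUC is computed
conditional on outcome status and is therefore prevalence-independent
by construction). Passing tests consequently show that the
correlation–discrimination mechanism behaves as described *under these
idealized conditions*; they say nothing about non-Gaussian or
mismeasured predictors, non-linear or interacting effects, calibration
(deliberately out of scope — only discrimination is studied), or
spectrum effects in real cohorts.

## Known limitations

* Exactly two predictors; the algebra (e.g. the closed-form SD of the
  linear predictor) is hard-coded to the bivariate case.
* Confidence intervals for AUCs are not produced — parameter
  uncertainty is not modelled, matching the design's intent.
* The unadjusted-OR closed form is only exact under common within-group
  variance; the warning path reports a conventional (control-SD) value
  rather than a derived one.
* Plotting is intentionally absent: sweep and matrix results are
  returned as arrays/DataFrames and written as CSV, ready for any
  plotting layer.
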