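# Methods

## The two-step model

`growthqr` estimates SNP marker effects on the parameters of individual
growth curves, at chosen quantiles of each parameter's distribution.

**Step one.** Each animal's weight–age series is fitted with the
three-parameter logistic w(t) = α₁ / (1 + exp((α₂ − t)/α₃)). In this
parameterization α₁ is the mature weight (kg, the horizontal asymptote
for α₃ > 0), α₂ the inflection age (days, where w = α₁/2) and α₃ the
growth scale (days, the reciprocal of the growth rate in the rate form;
at t = α₂ + α₃ the curve reaches α₁/(1+e⁻¹) ≈ 0.73·α₁). The scale form
(α₂ − t)/α₃ is the single internal convention; no rate form is stored,
and the genomic-curve predictor applies GEBV shifts to these same
parameters so the two steps stay dimensionally consistent.

Fitting is nonlinear least squares (Levenberg–Marquardt), relative
tolerance 1e-8 on the residual sum of squares, at most 200 iterations.
The self-start takes α₁⁰ = 1.05 × max weight, α₂⁰ = the linearly
interpolated age at which weight crosses α₁⁰/2, and α₃⁰ = the reciprocal
slope of logit(w/α₁⁰) on age, with a span/5 fallback when the series has
no usable slope. A fit is reported unconverged — never an exception —
when the optimizer fails, when the weights are constant (no curvature),
or when the fitted asymptote leaves the plausibility band
[max weight, 10 × max weight] without the fit being essentially exact.
Unconverged animals are excluded from step two with a logged count.

The fitted parameters are then corrected for the fixed effects sex, lot
and halothane genotype by an OLS model with categorical main effects
only (no interactions: the factors enter additively, the simplest
defensible design). The corrected trait is the OLS residual plus the
grand mean, so trait means are preserved exactly; a rank-deficient
(confounded) design triggers a warning and the minimum-norm solution.

**Step two.** For corrected trait y and dosage matrix X (0/1/2, raw —
the model carries an explicit intercept and no standardization), the
penalized quantile estimator solves

    min_{μ,β} Σᵢ ρ_τ(yᵢ − μ − xᵢ·β) + λ Σₖ |βₖ|,
    ρ_τ(u) = τu (u > 0), −(1−τ)u (otherwise),

with μ unpenalized because the penalty covers marker effects only. The
problem is solved exactly as a linear program (positive/negative splits
of residuals and coefficients; HiGHS backend, feasibility tolerances
1e-9). Exactness is the point: the solver is validated against a
brute-force vertex-enumeration oracle, and any optimal vertex is an
acceptable answer when the optimum is non-unique (tests compare
objective values, never coefficient vectors).

λ is selected per (trait, τ) over a grid (default 0–50 by 0.5) by
maximizing predictive capacity — the in-sample Pearson correlation
between fitted and observed trait values; ties resolve toward the larger
λ (the sparser model), and a λ whose fitted vector is constant is
rejected as having undefined capacity. In-sample selection is the
default deliberately; whether to cross-validate instead is left to the
caller (`select_lambda` accepts any y/X, so k-fold wrappers are
straightforward), since the capacity criterion itself does not specify a
holdout.

Goodness of fit is the quantile pseudo-R¹ = 1 − V_full/V_null, with
V_null the check loss at the sample τ-quantile (computed with the
inverted-CDF convention, the check-loss-minimizing order statistic; the
ratio is invariant to which point of the optimal interval is used).

**Inference.** Marker-effect uncertainty comes from a case (paired-row)
bootstrap: resample animals with replacement, refit the LP, take the SD
of each coefficient over replicates (default 200), and form two-sided
normal-approximation p-values 2(1 − Φ(|β̂|/se)). Only a standard error is
claimed, hence the normal approximation rather than percentile
intervals; a marker with zero bootstrap SD and a zero point estimate
gets p = 1. Identical seeds give bit-identical summaries.

**Prediction.** GEBV_i(τ) = xᵢ·β̂(τ) per trait. The genomic growth curve
of animal i plugs (μ̂ₛ + ûₛᵢ) into the logistic, where μ̂ₛ are the grand
means of the corrected traits; the population curve is the mean over
animals, excluding (with a warning) any animal whose effective growth
scale is zero. Confidence bands recompute the mean curve for each
bootstrap replicate of the effect vectors and take pointwise percentile
intervals (default 95%); band comparisons across τ are visual, not a
formal test. Ranked-marker tables keep the top ⌈fraction × p⌉ markers by
|effect| (ceiling, so 2.5% of a 237-marker panel is 6), ties broken
toward the lower marker index.

## The synthetic F2 generator

The generator emulates the study design the estimator targets: 345 F2
animals genotyped at 237 SNPs over six chromosomes (56/54/59/31/25/12
markers; evenly spaced over 170/130/120/90/60/50 cM, lengths on the
scale of pig linkage maps), weighed at 0/21/42/63/77/105/150 days.
Founder lines are fixed for alternate alleles, F1s are heterozygous
throughout, and each F2 genotype is the sum of two F1 gametes simulated
as a Markov walk with Haldane (no-interference) recombination fractions
r = (1 − e^(−2d/100))/2 — the simplest defensible LD-generating
mechanism for an F2; zero map distance means complete linkage. The X
chromosome is treated as autosomal and there is no genotyping-error or
selection model. True parameters are base values (90 kg, 113 d, 32 d,
matching the scale of corrected-trait means in F2 pig data) plus
additive marker effects plus covariate shifts; observed weights add
Gaussian noise with an age-indexed, non-decreasing SD schedule
(default 0.3/1.0/1.8/3.4/4.4/5.7/5.7 kg), reproducing the fan-shaped
spread of weight data over time. Non-positive weight draws are
resampled.

Quantile-heterogeneous marker effects are produced, when requested, by
multiplying the noise SD by exp(γ·z) with z the standardized dosage
score over the causal markers: animals carrying more effect alleles are
noisier, so the conditional quantiles of the phenotype depend on those
markers with τ-dependent slopes. The default is homogeneous effects with
heterogeneous age noise.

Two default scenarios are exposed. The study-scale `SimConfig` keeps the
full fan schedule, which is a *cross-animal* spread: it reproduces the
marginal look of real weight data but propagates to tens of kilograms of
step-one error on the extrapolated asymptote, so it is the right setting
for plumbing and distribution checks, not for marker recovery. The
`default_strong_signal_config` scenario (300 animals, 100 markers over
200 cM, 5 causal markers) instead uses within-animal measurement error —
the schedule scaled by 0.1, about 0.6 kg at 150 d — under which the
asymptote estimate carries roughly 2.5–3 kg of error, and causal effects
of 15 kg/allele sit at or above five times that residual-equivalent SD.
That is the regime in which ranking is expected to recover the causal
set; passing recovery tests say nothing about panels whose effects are
comparable to the step-one noise, and nothing about real LD structure,
which the map-distance walk only caricatures.

## Numerical choices and degenerate inputs

- LP optimality: HiGHS with 1e-9 feasibility tolerances; coefficients
  below 1e-9 in absolute value are snapped to zero before counting
  non-zeros. The reported objective is recomputed from the returned
  solution, so it is self-consistent by construction.
- Residual-sign counts in quantile-coverage checks treat |r| ≤ 1e-7 as
  zero, since LP vertices place residuals at exact zeros only up to
  solver tolerance.
- Quantile convention: sample τ-quantiles use the inverted-CDF method
  (a check-loss minimizer) wherever a single number is needed.
- Curve fitting is deterministic; every stochastic component (simulator,
  bootstrap, pipeline) flows from explicit integer seeds, and the
  pipeline derives per-(trait, τ) bootstrap seeds from the run seed.
- Missing genotype calls: hard error by default, since the genomic model
  needs complete dosages; opt-in per-marker mode imputation (ties to the
  smallest call) is available, and both behaviors name the offending
  cell or marker.
- Degenerate regression inputs raise early: empty problems, τ outside
  (0,1), negative λ, constant responses (undefined pseudo-R¹), constant
  fitted vectors (undefined capacity).

## Validation battery sizes

The acceptance script and test suite use problem sizes chosen to make
each property cheap but not trivial: 200 random tiny LP instances
(n ≤ 8, p ≤ 2) against the enumeration oracle; the full 101-point λ grid
on a 200×50 instance for the shrinkage path; 100 noise-free curve draws
for parameter recovery; and 20 independent 300-animal/100-marker seeds
for end-to-end marker recovery, with one marker-coupled run for
quantile-curve separation. These sizes are the package's own validation
design and can be scaled up freely through the same entry points.

## Known limitations

- Predictive capacity is in-sample; with p approaching n it rewards
  overfitting, and users selecting λ for prediction should cross-validate.
- The bootstrap refits one LP per replicate; at panel scale with the
  full λ grid this is the dominant cost.
- No quantile-crossing correction across τ: fitted quantile surfaces may
  cross, as in any independently-fitted quantile family.
- The multi-trait pedigree variance-component model sometimes paired
  with this design (heritabilities, genetic correlations) is out of
  scope; no pedigree machinery is included.
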