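# Methods

## Psychometric model

All disparities, thresholds and spreads are carried in log10 arcsec;
linear arcsec appears only at I/O boundaries.  The response model is the
scaled logistic

Ψ(x) = γ + (1 − γ − λ) · L(x; α, β),  L(x) = 1/(1 + e^(−β(x−α))),

with the guess rate γ fixed by the task (1/2 for 2AFC, 1/4 for 4AFC) and
the lapse rate λ multiplying the upper asymptote as 1 − λ.  λ is the
probability of an *incorrect* response due to a lapse; the probability of
lapsing at all, λ\*, satisfies λ = λ\*(1 − γ) and is exposed only through
conversion functions, never stored in a model.  The spread σ is defined by
the central 95% rise of the base logistic (0.025 → 0.975), fixing
β·σ = 2 ln 39 ≈ 7.3271; this reproduces every spread/slope pair the
package quotes (σ=1 ↔ β=7.327, σ=1.7 ↔ β=4.3, σ=1.5 ↔ β=4.9).  The
threshold θ is the disparity where Ψ = π (π = 0.75 throughout, for both
tasks); the location α follows from θ as
α = θ − ln(F/(1−F))/β with F = (π−γ)/(1−γ−λ).  Probabilities are clipped
to [1e−12, 1−1e−12] before logarithms in all likelihood computations; at
the parameter scales involved this never changes a result, it only
protects against log(0) at extreme grid corners.

## Up/down staircase

The data-collection staircase is weighted one-up/one-down: −0.15 log10
arcsec after a correct response, +0.45 after an error, converging on the
level where P(correct) = 0.45/(0.45+0.15) = 0.75.  Sessions start with a
cued practice trial at 3.0 log10 arcsec (1000 arcsec); in simulation the
cue is modelled by responding correctly with probability max(Ψ(3.0),
0.95), and the trial is flagged so fits can exclude it (the default).
Levels are clamped to [0, 3] log10 arcsec — the display cannot exceed the
1000-arcsec starting disparity, and thresholds of interest lie well
inside.  Trial counts are fixed (no reversal-based termination).

## Bayesian adaptive procedures

All procedures share one grid machinery.  The default grid: threshold
axis [0, 3] log10 arcsec in steps of 0.01, stimulus candidates identical
to the threshold axis; where a spread axis exists, 21 log-spaced values
over [0.03, 3.5] (the empirically observed range of fitted spreads);
where a lapse axis exists, {0, 0.01, …, 0.06} (the fitting constraint
range).  Grids are ordinary constructor arguments, so any study can
substitute its own.  The grid is parameterized by the *threshold at π*
rather than the logistic location, so every hypothesis satisfies
Ψ(θ) = π by construction and the posterior over θ is directly the
posterior over the reported quantity.

Priors are uniform over the threshold axis always; over the spread axis
either uniform (mass equal at the grid points) or Gaussian (the normal
density evaluated at the grid values and renormalized), independent
across axes.  Updating is Bayes' rule with the per-trial Bernoulli
likelihood; the posterior is renormalized after every update and checked
for degeneracy.

Placement rules: the ZEST family (fixed-spread ZEST and both ZEST-2D
variants) places each trial at the posterior mean of the threshold
marginal, snapped to the nearest stimulus candidate; the Psi family
places at the candidate minimizing the expected entropy (bits, 0·log 0 =
0) of the updated posterior's marginal over the parameters of interest,
with the expectation over the two responses taken under the current
posterior's predictive probability.  Entropy ties break toward the
smaller intensity, deterministically.  Estimates are posterior means of
the relevant marginals at every trial; there is no dynamic stopping.
The two ZEST-2D variants share one posterior and placement rule and
differ only in whether the spread is reported as an estimate or treated
as a nuisance parameter.  Psi (θ,σ) and Psi θ(σ) fix the lapse at the
task's model value (0.02 for 2AFC, 0.03 for 4AFC, both λ\* = 0.04); the
lapse-marginalizing configurations put a uniform prior on the lapse axis.

With a uniform prior the posterior mode equals the exhaustive grid
maximum-likelihood estimate; the test suite asserts this on simulated
sessions, and asserts the entropy placement against a brute-force oracle
on grids up to 10×10×5.

A vectorized batch runner executes fixed-spread ZEST staircases as a
posterior matrix over runs; it is bit-compatible with the scalar path
when both consume the same pre-drawn uniforms (asserted in the suite),
and makes population-scale sweeps (hundreds of thousands of staircases)
run in seconds.

## Maximum-likelihood fitting

Session logs are aggregated to per-level (n, k) counts and fitted with
three free parameters (θ at π = 0.75, σ, λ) by Nelder–Mead simplex search
on the negative log-likelihood, with γ fixed.  Constraints (σ > 0,
0 < λ < 0.06) are enforced by transform — log σ and a scaled logistic for
λ — so the simplex never meets a boundary; a large-finite-penalty path
exists for direct probe evaluations.  Twelve starts cover a coarse 2×2
lattice of threshold/spread values crossed with λ ∈ {0.001, 0.02, 0.05};
the best likelihood wins.  Because the internal parameterization is
already (θ at π, σ, λ), no post-hoc conversion of the reported threshold
is needed.

Goodness of fit is the deviance against the saturated binomial model,
Dev = 2 Σ[k ln(k/(n p̂)) + (n−k) ln((n−k)/(n(1−p̂)))].  Its p-value is a
parametric bootstrap: B datasets (default 1000) simulated from the fitted
model at the same design, each *refitted* with a warm-started simplex,
and p is the fraction of refitted deviances at least as large as the
observed one.  Refitting matters: comparing against non-refitted
deviances ignores the three fitted degrees of freedom and makes the test
strongly conservative (fraction of p < 0.05 under the true model ≈ 0.005
instead of 0.05); the warm-started refit brings calibration to ≈ 0.02,
with the residual conservatism due to the single-start refit versus the
multi-start original fit.  The cheap non-refit variant remains available
as `refit=False`.  Fits are screened by θ ∈ [1, 500] arcsec,
σ ∈ [0.01, 7], p(Dev) > 0.05.

At 2000 trials with three free parameters, the Cramér–Rao bound for σ̂ on
an equal-allocation design spanning the function is ≈ 0.12 log10 arcsec;
the fitted σ̂ reaches that bound empirically.  Threshold recovery is much
tighter (SD ≈ 0.02), and θ̂-bias shrinks with trial count on
staircase-collected data.

## Synthetic observer populations

Three built-in profiles summarize the experiments the package models
(2AFC global, n=71; 4AFC global, n=68; 4AFC local, n=76) by the mean/SD
of thresholds (1.528±0.300, 1.540±0.203, 1.568±0.230 log10 arcsec),
spreads (1.005±0.776, 1.186±0.740, 1.306±0.632) and λ\*
(0.0207±0.042, 0.0308±0.0361, 0.0276±0.036), with spread-on-threshold
regressions σ = −0.823 + 1.305·θ and σ = −0.159 + 0.934·θ for the two
4AFC profiles (threshold and spread correlate positively in 4AFC; the
2AFC spread is sampled independently).

Marginals are truncated normals on the validity ranges (θ within
[1, 500] arcsec, σ within [0.01, 7], λ\* within [0, 0.08]).  Because
truncating N(mean, SD) shifts its moments — for the heavily
left-truncated 2AFC spread distribution by ≈ +0.15 — the generator
*solves* for the underlying (loc, scale) such that the truncated
distribution has the target mean and SD.  For λ\* the target SD is
unreachable: no distribution supported on [0, 0.08] can combine mean
0.0207 with SD 0.042 (the maximum is ≈ 0.035), so the solver weights the
mean heavily, matches it exactly, and lets the SD saturate near the
family maximum.  For the regression-generated 4AFC spreads the residual
SD is back-solved from SD_σ² = b²·SD_θ² + SD_ε², preserving the marginal
spread SD.  λ is always derived from λ\* per task, keeping
λ = λ\*(1 − γ) exact.

What the generator does not emulate: the real distributions' skew and
heavy lapse tail (truncated normals are a stand-in and are exposed for
replacement), test–retest variability, age structure (spreads were found
independent of age), and non-stationary observers.  Passing tests on
these populations therefore validate the estimation machinery under the
printed population moments, not distribution-shape effects.

Real per-subject tables (CSV or XLSX) load through a schema-tolerant
reader (column aliases for id/θ/σ/λ/task, log10 or arcsec threshold
units); rows outside the validity ranges are dropped and counted.

## Monte-Carlo experiments

Threshold bias is θ̂ − θ_S in log10 units; its antilog (the *bias
factor*) is the multiplicative error in arcsec.  For a population,
per-observer mean bias is averaged *unweighted* across observers; the
quoted SD is the SD of the pooled per-run bias distribution (the pooling
is a reporting choice; per-observer means are retained in the summary so
across-observer SDs can be formed as well).  The percentile sweep
evaluates assumed spreads at the 5th–95th percentiles (step 5, linear
interpolation between order statistics) of the observers' spread values
and selects the argmin of |mean bias × SD|, ties toward the smaller
spread.  Seeds flow through a single `numpy` generator, making every
summary bit-reproducible.

Problem sizes: acceptance-style runs use 1000 simulations for the
single-observer benchmarks and 200 simulations per observer per
percentile for the sweep; mismatch surfaces use 500–2000 runs per point.
The entropy search in Psi-family benchmarks uses a threshold step of 0.02
and a stimulus step of 0.05 (the default 0.01 grid is available when
single runs, rather than thousands, are needed).

## Known behavior and limitations

* Fixed-spread ZEST with an over-estimated spread (σ_M = 1.5 on a
  σ_S = 1 observer, 4AFC) carries a small positive finite-sample bias
  (factor ≈ 1.015 at 20–30 trials) that vanishes when σ_M = σ_S; the
  mismatch-bias asymmetry (steep-side bias grows several times faster per
  unit of mismatch than shallow-side, positive in 2AFC and negative in
  4AFC) is reproduced.
* Single-run threshold estimates at 20–30 trials carry ≈ 0.09–0.13 log10
  arcsec of sampling SD for all procedures; this is at the information
  bound for the per-trial Bernoulli likelihood and no estimator
  configuration on these grids reduces it materially.  Population-level
  quantities (means over observers, across-observer SDs of mean bias) are
  correspondingly tighter (≈ 0.015–0.05).
* With the threshold grid centered on the true threshold, posterior-mean
  estimators are near-unbiased for all procedures at these trial counts;
  Psi-family overestimation reported elsewhere depends on the prior
  support and grid placement of the implementation, and is not a property
  of the entropy rule itself on a symmetric grid.
* The |bias × SD| product is very flat above the ~60th spread percentile
  for 2AFC populations, so at scaled-down simulation counts the argmin
  can drift within the 60–95% region; the qualitative recommendation
  (choose the 60–80th percentile of the spread distribution) is stable.
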