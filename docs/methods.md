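# Methods

## The model

A randomly stopped sum is `S_j = Z_1j + ... + Z_{N_j j}`: subject `j`
contributes a random count `N_j` of positive magnitudes `Z_ij`, and the
analysis couples three log-link models — for the counts, for the
magnitudes, and for the sums. The marginal law of `S` is a compound
distribution (a mixture over `n` of n-fold convolutions of the magnitude
law) with no closed form in general; the package approximates it by
simulation rather than by Panjer recursion, Fourier convolution or
Gaussian approximation, which are out of scope.

Key structural facts the implementation relies on:

* **Log-link additivity.** If all three models use the log link and the
  frequency and magnitude models share a predictor, the sums model's
  coefficient for it is `ω = α + β`. This is exact for the conditional
  mean (`E[S|x] = E[N|x]·E[Z|x]` by Wald's identity) and is the main
  interpretive device throughout.
* **Conditional closure.** Gamma magnitudes gamma(ρ, ς) give
  `S | N=n ~ gamma(nρ, ς)` (the GG model; the exponential is the ρ=1
  special case); inverse-Gaussian IG(θ, κ) gives `IG(nθ, n²κ)`;
  log-normal magnitudes have no closed conditional sum, and the LN model
  treats the sum as approximately log-normal — a standard and generally
  well-behaved approximation for sums of log-normals.
* **Moment identities.** `E[S] = E[N]E[Z]` and
  `Var[S] = E[N]Var[Z] + Var[N]E[Z]²`; both are enforced as tests of the
  simulator.

## Parameterizations and defaults

* Negative binomial counts are stored as (event probability π, scale ϕ)
  with mean `θ = ϕπ/(1−π)` and variance `ω² = ϕπ/(1−π)²`; the
  variance/mean ratio is `1/(1−π) > 1`, the over-dispersion this family
  exists to absorb. Converters to and from the (mean, dispersion)
  convention are provided. The study baseline is (π=0.5, ϕ=10): mean 10,
  variance 20 — typical of counted responses such as fixations per
  stimulus.
* Magnitude baselines emulate human response times in milliseconds with
  mean ≈ 1000 and SD ≈ 500: log-normal(μ_log=6.81, σ_log=0.447) or
  gamma(shape 4, scale 250). Gamma is (shape, scale); the inverse
  Gaussian is (location = mean θ, shape κ), matching its closure rule.
* Counts of zero are legal draws (P(N=0) = (1−π)^ϕ ≈ 0.001 at baseline).
  They are retained by frequency fits and dropped by magnitude and sums
  fits, where `log 0` is undefined — the minimal convention, applied
  consistently in the GLMs, the bootstrap and the power engine.

## Frequentist fitting

The frequency model is a log-link Poisson or NB2 negative binomial GLM
(dispersion estimated by ML jointly with the coefficients) via
statsmodels. The magnitude model honors the two-level structure by
subject-level aggregation: the analysis unit is the subject and the
response is the subject's **mean magnitude**, modeled on the log scale
(LN) or by a log-link gamma GLM (gamma/exponential). A random-intercept
mixed model on log magnitudes is available as an opt-in mode; the
default was chosen because the study's generative model places no
between-subject variance beyond sampling, and because the subject-mean
formulation ("predicting mean duration") reproduces the reference power
values markedly better than the mean-of-logs alternative. Wald tests
(z, two-sided) are used throughout; magnitude-model log-likelihoods are
evaluated at the observation level so that families (e.g. exponential
vs log-normal) are comparable on the same data.

The simulation estimator is a parametric bootstrap: frequency and
magnitude specs are fixed at their supplied values; each replicate
simulates all subjects' sums and fits the sums GLM; percentile
intervals at 95% summarize the coefficient draws. Percentile was chosen
as the natural reading of simulation quantiles; the level is
configurable. Replicates with non-convergent fits or all-zero counts
are skipped, logged, and reported via an effective replicate count.

## Bayesian hierarchical estimator

The joint model (per unit `u` — a subject, or a subject-round cell in
the three-level case):

```
n_u   ~ Poisson(λ_u),   λ_u ~ Gamma(q, q/η_u),   log η_u = X_f α
GG:   Z_i ~ Gamma(q_m, q_m e^{−μ_u}),   LN:  log Z_i ~ N(μ_u, σ²)
      μ_u ~ N(X_m β, σ²_υ)
GG:   S_u ~ Gamma(λ_u q_m, λ_u q_m e^{−μ_Su}),  μ_Su = μ_u + log λ_u
LN:   log S_u ~ N(X_s ω, σ²_s)
```

The gamma-mixed Poisson marginalizes to a negative binomial with
over-dispersion 1/q. In the GG variant the sums location is the exact
identity `μ_S = μ + log λ` (asserted per draw in the tests) and the sums
coefficients are derived as `ω = α + β`; all three likelihood layers are
included simultaneously, which means the sums layer re-uses the same
observations the magnitude layer uses — that is the integrated model's
own construction, and its practical consequence (tighter posteriors for
q and the locations than a non-integrated fit would give) is inherited
deliberately. In the LN variant the sums layer has free coefficients ω
and free variance σ²_s, because the log-normal sum is an approximation
with no exact identity to enforce. Three-level data give the magnitude
and sums layers per-round intercepts while the frequency layer keeps a
single coefficient vector.

"Uninformative" priors are made concrete as N(0, 100²) on all
regression coefficients, Gamma(0.01, 0.01) on the shapes q and q_m, and
Gamma(0.01, 0.01) on the precisions of every variance component — the
standard BUGS-style diffuse choices. Exact hyperparameters are not
identified by any reference value, so these are conventions, not fits.

The sampler is blocked Gibbs with adaptive random-walk Metropolis for
non-conjugate blocks:

* conjugate draws for β, the variance components, the LN ω, the LN μ_u,
  and (LN) λ_u;
* in the LN variant, α and q are updated against the λ-marginalized
  (negative binomial) likelihood — a partially collapsed step that
  removes the slow α↔λ random walk of the centered parameterization —
  and λ is then redrawn conjugately;
* in the GG variant, λ_u and μ_u get componentwise vectorized Metropolis
  updates (their conditionals include the sums layer), and q, q_m, α get
  scalar/componentwise Metropolis.

Proposal scales adapt toward 44% acceptance during burn-in only, so the
retained draws target the exact posterior. Convergence is monitored by
split-R̂; any monitored parameter above 1.05 raises a warning. Defaults
are 2 chains, 5,000 burn-in, 10,000 draws; the tests run reduced chains
(600–800 burn-in/draws) at reduced data sizes, which the pilot coverage
runs showed to be adequate for the coefficient blocks.

DIC is reported per submodel as `Dbar + pD` with
`pD = Dbar − D(posterior means)`, where the deviance of each layer is
−2 × its log likelihood evaluated at the latent unit-level parameters —
the convention under which the frequency, magnitude and sums models can
be compared simultaneously. Posterior predictions incorporate the
unit-level random terms (λ_u, μ_u), so GG predicted sums track observed
sums with R² > 0.99 on well-specified synthetic data; LN sums
predictions are fixed-effects only and correlate less tightly, matching
the behavior expected of that variant.

**Observation-level predictors.** The extension adds
`τ_ij = Σ_p δ_pj w_pij` to the magnitude location with random
coefficients `δ_pj ~ N(η_p, σ_p²)`, and adds the per-unit totals
`Σ_i τ_ij` to the sums location. The sums term follows the additive
link-scale bookkeeping literally; it is an approximation (the effect of
obs-level shifts on the log of a sum is not the sum of the shifts), so
recovery of η_p is cleanest when the predictors are centered within
units — the configuration the tests use. LN updates for δ are conjugate;
GG updates are componentwise Metropolis.

## The power-study engine

Design: two conditions with equal per-condition sizes
N ∈ {25, 50, 100, 200}; control at the baselines above; treatment specs
shifted by `d` × (baseline natural SD) on the natural-scale mean, with
the secondary parameter held fixed (negbin keeps ϕ and re-solves π;
log-normal keeps σ_log; gamma keeps its shape). This mapping is recorded
in every output manifest. `d` spans ±0.2, ±0.5, ±0.8 ("small", "medium",
"large"). Per replicate the three models are fit with a condition
indicator and the two-sided Wald z of the condition coefficient is
recorded at α = 0.05; rejection rates across replicates (default
10,000) estimate Type I error or power, with binomial MC standard
errors.

For throughput the two-group log-link fits are evaluated in closed form
and vectorized across replicates: a saturated two-group design makes
the fitted group means equal the sample group means for every family
used (this is the ML score equation, not an approximation), the NB2
dispersion solves a one-dimensional profile score by vectorized
bisection, and Wald SEs come from the information matrix — which at the
MLE coincides with the observed Hessian block, the β–dispersion cross
term vanishing there. The tests verify agreement with statsmodels
NegativeBinomial/OLS/Gamma-GLM z statistics to four decimals on
individual replicates. A full Type I or power cell at 10,000 replicates
runs in about one to ten seconds on one CPU.

## The synthetic-data generator

`generate_fixture` realizes the generative model the estimators target:
subject-level (and optionally round-level) covariates enter the
log-mean of a negbin/Poisson/gamma-mixed count law and the log-location
of a log-normal/gamma/exponential magnitude law; optional N(0, σ_υ)
unit-level noise on the log-location; per-round intercepts for
three-level data. Defaults are the study baselines. True parameters are
recorded in the dataset metadata, and regeneration from (config, seed)
is byte-identical.

What it does *not* emulate: autocorrelated magnitudes within a subject,
heteroscedastic random coefficients, non-ignorable zero counts,
measurement error in predictors, or any vendor-specific structure of
real eye-tracking records. Tests passing on these fixtures therefore
establish internal correctness and calibration of the estimators under
the stated model, not robustness to those real-data features.

## Numerical choices

* NB2 profile shape is bisected on θ ∈ [10⁻², 10⁶] in log space
  (40 iterations); boundary solutions (under-dispersed replicates) pin
  at the Poisson-like end.
* Skewness in diagnostics is the adjusted Fisher–Pearson sample
  skewness; bootstrap-draw outliers are draws beyond 3 IQRs of the
  median.
* Quantiles use numpy's default (linear interpolation); percentile
  bootstrap intervals use the empirical 2.5/97.5 quantiles.
* All randomness flows through numpy Generators; scenario grids and the
  acceptance script derive independent child seeds via `SeedSequence`.

## Known limitations

* The LN sums model is an approximation; its residual diagnostics (log
  scale) and quantile comparisons are the intended guard-rails.
* Reference Type I rates for gamma-distributed magnitudes show a sums
  inflation (~0.06) that persists at N = 200; a pooled two-group Wald
  test on i.i.d. per-subject sums is asymptotically exact under the
  null, so this package's direct fits show only a mild small-sample
  version of it (~0.055 at N = 25). Power for sums under strong
  *negative* frequency effects is likewise somewhat below the reference
  values. Both are properties of the direct-GLM reading of the sums
  test; alternative readings (count-weighted fits, deviance- or
  ML-shape dispersions) were evaluated and match the reference pattern
  worse overall.
* The GG variant's simultaneous likelihood layers re-use data (see
  above); its q posterior is correspondingly concentrated and can sit
  below the generating negbin scale — coefficient coverage, which is
  what the acceptance tests gate on, is unaffected in the tested
  regimes.
* MCMC adaptation is frozen after burn-in but the burn-in defaults are
  heuristics; models far from the tested sizes may need longer chains
  (watch the split-R̂ warning).
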