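# Methods

## The index

The Absolute Thinking Index for week *t* is the unweighted arithmetic mean of
the relative search volumes of all dictionary terms at *t*, kept on the raw
0–100 scale so that effects read directly in index points. Accent-variant
query series (e.g. a French term extracted both with and without its
diacritics) enter the average as separate items rather than being merged:
the packaged French dictionary of 19 terms therefore yields 21 series.
Reliability is summarised by Cronbach's α with the sample-variance (n−1)
convention for both item and total variances; α is attached to every index
build, and a value below a caller-supplied threshold (or an uncomputable α,
as for an all-constant panel) raises a logged `ReliabilityWarning` rather
than failing or passing silently.

The packaged English absolutist list is the published 19-word absolutist
dictionary; the French and Japanese translation files and the neutral-word
control pool are synthetic stand-ins with the documented structure (19
terms; exactly two accented French terms, "complètement" and "déjà"; a
diacritic-free pool). All lists are overridable by plain-text files, one
term per line.

## Search-volume data model

Weekly series are keyed by week-start date at exact 7-day spacing and bounded
in [0, 100]. The platform's sub-threshold cells (`"<1"`) are censored to 0 at
parse time and counted per file, so the sub-threshold prevalence of any input
is auditable. Censoring is a parse-time transform only — written files never
re-censor — and the panel writer emits full-precision decimal text so a
write/read round trip is bit-exact. Panels assemble series over the
intersection of week axes when axes differ only by leading/trailing
truncation; interior gaps and duplicate terms are errors.

## Synthetic data generator

The generator emulates the study's observables from a latent regional
distress process

    latent_t = μ + c₁·t̃ + c₂·t̃² + c₃·t̃³ + δ·1[t ≥ t₀] + AR(1) noise,

with t̃ the centered week index, φ the AR(1) coefficient (|φ| < 1, started
from the stationary distribution), and δ an additive level step from the
intervention week t₀ on. Defaults are the two-year single-geography study
conditions: 104 weeks, t₀ = 56, δ = 3.2 index points, μ = 85, φ = 0.6,
σ_lat = 1. A `france_validation` factory switches to the survey-validation
conditions (16 weekly waves × 12 regions, no intervention).

Observables are derived as follows.

* **Word panels** — raw_jt = λ·latent_t + Gaussian noise (σ_word = 2),
  max-normalised per term to [0, 100] over the full generated window (each
  series hits 100 at its own maximum week, mirroring the platform's
  within-query scaling) and then censored below 1. Negative raws are clipped
  at 0 and counted.
* **Survey panels** — depression% = intercept + region effect +
  γ·(latent − μ) + noise, bounded in [0, 100], with γ = 0.23 %-points per
  index point by default; anxiety follows its own quadratic-trend process
  (plus region effects and noise), independent of the distress latent, so
  the index tracks depression dynamics but not anxiety dynamics.
* **Covariates** — weekly deaths per million = intercept + b·(latent − μ) +
  noise, floored at 0; cases are either a scaled noisy multiple of deaths
  (default) or an independent positive series (null-link testbed). The
  helper `deaths_slope_for_target` inverts the stationary-variance algebra
  to choose b so that the standardized index-on-deaths slope has a desired
  expectation.

All draws flow from one seed through named substreams (latent / words /
survey / anxiety / covariates / controls), so identical configs reproduce
bit-identical data and components can be regenerated independently.

**The realised truth.** Per-term max-normalisation rescales the injected
step: a δ-point shift on the latent becomes roughly (100/max_raw)·δ points
on the observed index (≈1.07·δ at the defaults). The truth record therefore
stores the *realised* index-scale effect — the mean post-period difference
between the generated panel's index and the index of a counterfactual panel
rebuilt from identical noise draws with the step removed, both expressed
with the factual panel's scale factors. That realised value, not the nominal
δ, is the estimand recovery tests score against; using the counterfactual
panel's own scale factors instead would let the normalisation absorb part of
the step and understate the effect every analysis on the observed scale sees.

What the generator does **not** emulate: the platform's sampling error
(Gaussian term noise is a stand-in; the real noise model is unpublished),
per-user query logs, the demographic composition of the searching
population, and cross-term correlation beyond the shared latent. Passing
recovery tests therefore demonstrates the estimators' correctness under the
stated data model, not the field validity of the index itself.

## Association statistics

Pearson correlations carry Fisher-z 95% intervals with standard error
1/√(n−3) and two-sided p-values from the t distribution with n−2 df; *n* is
always the number of paired observations actually used. Detrending regresses
the z-scored series on the z-scored week index, so the reported slope is
bounded in [−1, 1] and comparable across measures (the raw-scale slope and
intercept are returned alongside); residuals are kept on the raw scale and
are exactly orthogonal to time. Residual correlations simply re-apply the
Pearson machinery to two detrended series — the diagnostic for associations
driven by a shared secular trend, which can flip sign after detrending. The
mental-health-symptom comparison index is built by the same averaging code
path over the symptom lexicon; it has no separate implementation.

## Mixed models

Estimation is restricted maximum likelihood via statsmodels `MixedLM`. With
no random terms the fit reduces exactly to OLS (tested against a
normal-equations oracle at 1e-8). Inference is Wald: normal-approximation
95% CIs and two-sided p-values per fixed term. The denominator-df
corrections some mixed-model software applies (Satterthwaite-type t tests)
are deliberately not reproduced; on the panel sizes used here the normal
approximation is anti-conservative by a few percent at worst, and the null
coverage calibration test bounds the damage. Every model is also refit on
fully z-scored data so raw-scale and standardized coefficients are always
both available; standardized estimates are invariant to positive rescaling
of any covariate.

Wave/week polynomials use centered raw powers (not orthogonal polynomials)
so coefficients remain interpretable against the model formulas. If the full
random structure fails to converge, random slopes are dropped one at a time
down to a random intercept, each step logged and recorded in the result's
`fallback_notes`; a single-group dataset with random terms is an error, not
a silent fit. Rank-deficient fixed designs fail with the offending columns
named.

## The counterfactual model

The impact estimator fits, on the pre-event weeks only,

    y_t = μ_t + β′x_t + ε_t,   ε_t ~ N(0, σ_ε²)
    μ_t = μ_{t−1} + η_t,       η_t ~ N(0, σ_η²)

— a local level plus a static regression on control-word series, the minimal
structure for the synthetic-control logic. Controls enter either as their
cross-word average (default; with ~19 interchangeable noisy controls the
average is the better-conditioned regressor), per word, or both, and are
standardized on **pre-period statistics only** so no post-period information
leaks into the fit. A deterministic trigonometric weekly-seasonality block
can be toggled on (off by default: the generator produces no seasonality and
the method's logic does not require it).

Posterior sampling is Gibbs: states by forward-filter backward-sampling,
variances by conjugate inverse-gamma updates, regression weights by a
conjugate normal (ridge) update — a deliberate simplification relative to
spike-and-slab regression priors, which matter when selecting among many
heterogeneous controls but add nothing with ≤ 20 exchangeable ones. Priors
are weakly informative and scale-following: inverse-gamma with 2 pseudo-
observations centred at 0.8·sd_pre (observation noise) and 0.1·sd_pre
(level innovation), and a N(0, sd_pre²) prior per regression weight. The
level is initialised diffusely (variance 10⁴·var_pre around the pre-period
mean). Defaults: 1000 draws, 100 burn-in, all randomness from one seed.
Because every draw is a deterministic transform of standard variates, the
estimator is exactly scale-equivariant and bit-reproducible under a fixed
seed.

Each retained draw propagates the level over the post-period, adds β′x_t for
the observed controls and observation noise, and yields a posterior
predictive counterfactual; the absolute average effect is the posterior mean
of the per-draw post-period average of y_t − ŷ_t, with percentile credible
intervals. The one-sided tail probability (the posterior mass on the other
side of zero from the point estimate) is floored at 1/(retained draws + 1).
Degenerate posteriors (variance draws collapsing at the numerical boundary)
raise an error with diagnostics rather than returning a fit. One-step-ahead
pre-period residuals at posterior-mean parameters are reported as a sanity
diagnostic.

## Problem sizes and numerical choices

Recovery and calibration suites run at the study's own dimensions — 104-week
panels with 19 terms and 19 controls, 16-wave × 12-region survey panels —
with replicate counts (20 for impact recovery and null calibration, 50 for
the survey-slope recovery, 25 for trend discrimination) chosen to give
stable pass/fail behaviour at desk scale. The Gibbs sampler uses 400–600
draws in the test suites and 1000 by default in the API. Ties and degenerate
inputs are handled explicitly: constant panels make α uncomputable (warning,
α recorded as missing), |r| = 1 collapses the Fisher interval onto r,
zero-variance regressors are dropped from the control set, and constant
pre-period targets are rejected.

## Known limitations

* The headline real-data estimates in the literature come from unarchived
  search-platform extractions and proprietary survey microdata; this package
  reproduces the *method* and verifies it on synthetic ground truth, not
  those point estimates.
* Wald inference in the mixed models is slightly anti-conservative at small
  group counts (see above).
* The BSTS component structure, priors and iteration counts are this
  package's own design choices, surfaced in `ImpactConfig`; published
  analyses using other reference implementations may differ in detail.
* Japanese term lists are opaque strings: no variant expansion is attempted
  across the two character systems, and the packaged translation is a
  stand-in.
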