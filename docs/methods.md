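# Methods

This note documents the statistical model, the synthetic-data generator
that stands in for the proprietary upstream data sources, and the
numerical and design choices a maintainer would want to know about.

## 1. The measurement pipeline

The pipeline converts a geotagged, classifier-scored image stream into a
county-week behavioral panel in four steps:

1. **Precision filter.** Posts geotagged at country or state precision are
   dropped (their bounding boxes cannot identify a county). Drops are
   counted and reported, never silent.
2. **County resolution.** City-level posts resolve to the county covering
   the greatest share of the city's population; exact ties break to the
   lexicographically smallest FIPS so resolution is deterministic and
   auditable. Neighborhood/POI posts carry a county directly — the
   synthetic stream supplies it, and real-data point-in-polygon lookup is
   out of scope.
3. **Thresholding.** An image counts as a mask image when its classifier
   score is **at or above** the decision threshold (boundary inclusive;
   the convention is arbitrary and documented here once). The operating
   threshold is chosen by the rule: among thresholds whose F1 is within
   `f1_tolerance` (default 0.01) of the best F1, take the one with the
   highest precision, largest threshold on ties. With the published
   five-row threshold table this rule selects 0.9. Undefined
   precision/recall (zero denominators) are flagged NaN, never coerced
   to 0.
4. **Rollup.** Per (user, county, week): posted ≥ 1 image, posted ≥ 1
   mask image. The county-week statistic is the ratio of user counts. A
   user active in two counties in one week counts in both denominators
   (the alternative — assignment to the modal county — would make the
   statistic depend on cross-county post ordering; pooling to the national
   series then remains a simple sum of county numerators and
   denominators). County-weeks with zero image-posting users are
   *missing*, not 0, and are excluded from model fitting.

Mandate exposure is coded on Monday–Sunday study weeks with the Thursday
rule: exposed iff a county- or state-level mandate took effect on or
before that week's Thursday (boundary inclusive). State mandates apply to
every county in the state; exposure is the union of the two levels.
Repeals are outside the data model — the study window largely precedes
them — so exposure is monotone within county. Dates are civil dates; no
timezone arithmetic.

## 2. The panel model

For county j, week t: `y_jt ~ Binomial(n_jt, p_jt)` with

```
logit p_jt = x_jt' β + u_county(j) + u_state(j) + u_week(t),
u_f ~ N(0, σ²_f) independently for county, state, week.
```

Fixed effects (reporting units in parentheses, coefficients per raw unit —
covariates are deliberately not standardized, so printed estimates match
the scales of the published summary tables): intercept; mandate (0/1); GOP
vote share 2016 (percentage points); mandate × GOP; lagged weekly COVID
deaths per 10k residents; urban population share (pp); population density
(persons/sq mi); national COVID news intensity (mentions per show);
retail visits per hundred residents; and a linear week counter. The three
random intercepts are crossed; county nesting within state is absorbed by
the state intercept, matching the separate county/state/week variance
components reported for such models.

### Estimation

No installed Python library fits a binomial GLMM with three crossed
Gaussian random intercepts by (approximate) maximum likelihood, so the
fitter is implemented here:

* **Inner loop (PIRLS).** Given variance components, the joint mode of
  (β, u) maximizes the penalized binomial log-likelihood. Newton steps use
  the exact Hessian `A'WA + P` (A = [X Z] sparse, W = n·μ(1−μ),
  P = blockdiag(0, σ⁻²)), with step-halving, and iterate until the Newton
  decrement is below 1e−9. The tight tolerance matters: the outer
  optimizer differentiates this profiled objective by finite differences,
  and a sloppy inner solve poisons that gradient (empirically it collapsed
  the three variance components onto a common value).
* **Outer loop.** The Laplace log-likelihood
  `ℓ(θ) = ℓ_pen(û) + const − ½ log|I + Σ^{1/2} Z'WZ Σ^{1/2}|`
  is maximized over θ = log σ_f with L-BFGS-B (bounds log σ ∈ [−6, 2.5],
  finite-difference step 1e−5, warm-started inner solves). Profiling β
  into the inner loop keeps the outer problem 3-dimensional; with the
  large binomial denominators of this design the joint-mode β is
  numerically indistinguishable from the fully profiled optimum (the test
  suite pins agreement with `lme4::glmer` — default Laplace — to a
  fraction of a standard error on every coefficient, and the
  log-likelihood to a few units; on study-scale panels they agree to
  0.01).
* **Uncertainty.** Fixed-effect covariance is the β-block of the inverse
  joint Hessian at the optimum — the standard conditional approximation
  for Laplace fits (what `vcov` reports in lme4). Wald intervals
  throughout. `k` for AIC/BIC counts fixed effects plus estimated variance
  components.
* **Degenerate cases.** With all variance components pinned at zero the
  model reduces exactly to an ordinary binomial GLM (verified against
  statsmodels to 1e−4 and machine-precision log-likelihood).
  Non-convergence of either loop sets `converged = False` on the results
  object; downstream consumers (pipeline, CLI) refuse to proceed silently.

### Marginal effects and effect translations

The mandate marginal-effect curve is the response-scale difference
`expit(x₁'β) − expit(x₀'β)` with mandate on/off at each GOP grid value,
all other covariates at the fitted sample means and random effects at
zero (a population-median county); the 95% band is by the delta method,
which the tests check against a 2000-draw sampling of the coefficient
distribution (band widths agree within 20%). The per-SD effect
translation `100·(exp(β·Δ) − 1)` is the odds-scale percent change; for an
outcome prevalence near 1% it approximates the percent change in
prevalence itself.

## 3. The synthetic-data generator

The generator emulates, with one root seed fanned out into named
substreams (gazetteer, schedule, covariates, effects, tweets, survey,
images), every input the pipeline consumes. Its defaults are the study
conditions of the county-week analysis, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| counties / states / weeks | 300 / 45 / 22 | the analysis panel's dimensions |
| β (fixed effects) | interaction-model column of the published fit | simulation truth for recovery |
| σ²_county, σ²_state, σ²_week | 0.037, 0.014, 0.027 | published variance components |
| users per county-week | Poisson, mean 650 × relative population, floored at 519 | every panel county clears the power-analysis floor, emulating the populous-county screen |
| image-level positive rate | 0.011 | observed share of mask images in a hand-checked 1000-image sample |
| score distributions | Beta(0.20, 0.04) positives, Beta(0.03, 1.50) negatives | grid-searched so thresholding at 0.9 yields precision ≈ 0.93, recall ≈ 0.77 at positive rate 0.011 |
| GOP vote share | Uniform(23.7, 85.1) | the all-county 95% interval; the summary tables give intervals, not distributions |
| urban share | Uniform(0, 100) | implies an SD (≈29 pp) close to the reported 25 pp |
| density | LogNormal(4.76, 1.59) | matches the all-county 95% interval (≈5–2600 /sq mi) |
| deaths, retail, news | autocorrelated AR(1)-driven nonnegative series | stationary 95% ranges approximate the published intervals; weekly covariates in observational panels are strongly autocorrelated |
| mandate adoption | P(adopt) logistic in GOP share, slope −0.04/pp; adoption date uniform after week 1; 30% of states add statewide mandates | mandates arrived earlier in Democratic-leaning areas; making this confounding explicit (and tunable) is the point of the generator |
| survey | pct = 10 + 35·(100·latent) + N(0, 2), clipped to [0, 100] | surveys report much higher levels (40–70%) than the posting rate (0.5–2%) but track the same latent trend |

Tweet-stream details: each image-posting user posts one image session per
week (user-level multiplicity is unspecified upstream, and the statistic
deduplicates by user anyway) plus Poisson(0.5) textless tweets; geotag
precision is drawn per tweet (4% country, 3% state, 55% city, 25%
neighborhood, 13% POI), so roughly 7% of tweets are dropped by the
precision filter; 14% of cities spill into a second county, with the home
county always holding the majority share so county resolution is exact
for stream-generated tweets.

Two simulation routes exist by design. `simulate_tweets` produces the full
event stream for exercising the measurement pipeline; `simulate_panel`
draws county-week counts directly (`n ~ Poisson`, `y ~ Binomial(n, p)`),
which is the exact aggregate of user-level Bernoulli draws and is what the
recovery study and acceptance script use — fitting 100 study-scale panels
takes ~90 s where the full stream would need millions of events per
replicate.

**What the generator does not emulate** — hence what passing tests do not
show about real data: real geography (FIPS codes are arbitrary labels; no
point-in-polygon), user-level covariate correlation (who posts is
independent of mask propensity given the county), non-representativeness
of the platform population, within-user score correlation across weeks,
mandate repeals, measurement drift in the classifier, and survey
house effects beyond one affine transform. Classifier imperfection
attenuates the measured prevalence (at threshold 0.9 roughly 77% of true
mask posters are detected, partially offset by false positives), so
stream-based coefficient estimates are mildly attenuated relative to the
latent model; the recovery study therefore targets the count-level model,
and the stream path is checked for calibration (national weekly
proportions in the 0.5–2% operating band) rather than coefficient
recovery.

## 4. Study design utilities

* Required n rounds to the **nearest** integer: with full-precision normal
  quantiles the formula gives 518.8, with 3-decimal truncated quantiles
  519.3; both round to the published 519, whereas a conventional ceiling
  would print 520 on full precision.
* Odds ratios are crude 2×2 `ad/bc` with Wald log-scale intervals;
  any zero cell triggers the Haldane–Anscombe +0.5 correction (flagged);
  two zero cells on a diagonal are undefined and raise. The upstream
  analysis reports ORs without naming an interval method; Wald is the
  default crude choice.
* Case-control sampling keeps every mask event and at most `per_day`
  non-mask events per UTC calendar date, without replacement, seeded.
* Krippendorff's alpha uses the nominal-metric coincidence-matrix form
  with missing entries allowed; bootstrap CIs are out of scope.

## 5. Problem sizes and runtime

Chosen scales: tests exercise reduced worlds (24–80 counties, 8–12 weeks)
for unit behavior, a 10,000-county draw for the variance-component
calibration check, 100,000 images for the score-distribution operating
point, and the full 300 × 22 panel for design construction, the worked
example, and the recovery study (100 replicates; ~1 s per fit). The
end-to-end pipeline example runs a 25-county stream in ~6 s.

## 6. Known limitations

* The Laplace approximation is least accurate for small binomial
  denominators; the 519-user floor keeps denominators large, but applying
  the fitter to sparse panels (many `n_jt` < 30) would warrant adaptive
  quadrature or MCMC, neither implemented here.
* Variance-component uncertainty is not propagated into fixed-effect SEs
  (conditional covariance); with 300/45/22 groups the effect is small but
  nonzero, and intercept coverage is the most sensitive.
* The threshold-selection rule takes the reported F1 values as given; if
  F1 is recomputed from rounded precision/recall the near-tie structure
  of the published table shifts (two rows differ by ~0.02 rather than
  0.01), which is why the selection tests pin the printed F1 column.
* `pearson_correlation` assumes independent observations; for the weekly
  validation series the first-difference route is provided to blunt
  trend-induced spurious correlation, but no HAC correction is applied.
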