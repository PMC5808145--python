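# Methods

This note records the models, the synthetic study system, and the
numerical and design choices behind `richcast`, at the level of detail a
user needs to interpret its output.

## The observation model

Richness observations are modeled as

    y[s,t] = mu + a_s + b_o(s,t) + eps[s,t],

with crossed Gaussian random effects for sites (`a_s`, SD `sigma_site`)
and observers (`b_o`, SD `sigma_obs`) and iid Gaussian residuals (SD
`sigma_resid`). A Gaussian likelihood is used rather than a count
likelihood: within-site richness is underdispersed relative to Poisson or
binomial variation, and the mean (~51 species) is large enough that a
continuous error model is adequate.

Inference is blocked Gibbs sampling: `mu`, the site block, and the
observer block have conjugate normal full conditionals; the three
variances get inverse-gamma full conditionals under a half-t prior
(nu = 2, scale 25 species) on each SD, implemented with the Huang–Wand
auxiliary inverse-gamma hierarchy so every update stays conjugate. The
half-t was chosen over a half-normal of the same scale because it is
exactly conjugate in this scheme; at 25-species scale both are far flatter
than the likelihood and the posterior is indistinguishable at the panel
sizes used here. Defaults: 1,000 warmup iterations, 500 retained draws,
all seeded. A split-chain potential-scale-reduction factor is reported per
variance parameter; values near 1 (< 1.05 in practice at 300 sites)
indicate the chain has mixed.

Two estimator properties are worth knowing when reading the variance
partition. First, the posterior mean of `sigma_site^2` includes the
posterior uncertainty of the site effects themselves, so the site fraction
runs ~1–2 points above the generating fraction and the residual fraction
correspondingly below (e.g. ~8.4% recovered against a generating 9%).
Second, with AR(1) residual correlation and observers serving contiguous
multi-year stints, the observer effects absorb a small part of the
temporally correlated residual, shrinking the recovered residual SD by
~2% (3.52–3.57 against a generating 3.6). Both are properties of the
estimand, not sampler defects.

## Observer correction of forecasts

`corrected_richness_draws` subtracts each posterior draw of `b_o` from the
training data; downstream models are re-fit once per draw (configurable
via `model_draws`; the evenly thinned subset keeps the cost of 500 ARIMA
or GBM refits manageable) and the per-draw Gaussian forecasts are pooled
by the law of total variance with the unbiased between-draw variance.

A corrected model predicts typical-observer richness, but the held-out
observation still contains that year's observer effect. Test forecasts
therefore add back the draw's effect for observers already seen in
training, and for unseen observers (or unsurveyed site-years) use effect 0
while adding `sigma_obs^2` to the predictive variance. Without this step
correction systematically *hurts* on synthetic panels — training-period
observers often continue into the test period, and the uncorrected site
mean silently benefits from their bias — which inverts the expected
direction of the correction. With it, correction improves RMSE, coverage,
and deviance for the average and ARIMA models and barely moves the naive
model, whose last-value forecast already discounts retired observers.

The species-level models take the observer effect as a predictor instead:
each tree of a corrected random-forest SDM trains on a different posterior
draw of the training effects (one draw per tree, cycling), and the JSDM
takes the posterior-mean effect as one extra covariate in a single fit
(a deliberate economy over 500 refits of an already Monte-Carlo objective).

## Forecasters

* **Average**: site mean and sample SD (n−1 denominator); interval width
  constant in the horizon.
* **Naive** (random walk): last observed value; step SD from first
  differences of consecutive observed years only (gaps are flagged and
  skipped); interval width exactly proportional to sqrt(h); no drift term.
* **Auto-ARIMA**: differencing order d (max 2) chosen by repeated KPSS
  tests at the 5% level with the short lag convention
  `floor(4 (n/100)^{1/4})`; stepwise search in (p, q, intercept) from
  starts (2,2), (0,0), (1,0), (0,1), moving to the best AICc neighbor
  until no improvement, p and q capped at 5. Candidates are maximum-
  likelihood SARIMAX fits; AICc = AIC + 2k(k+1)/(n−k−1) with n the length
  of the differenced series. Non-convergent candidates are skipped; series
  under 10 points fall back to the average model with a warning. The
  search is deterministic given the series. No seasonal terms (yearly
  data) and no drift for the naive model; drift (an intercept under d=1)
  is allowed in the ARIMA search.
* **Richness GBM**: squared-error boosting, depth 5, shrinkage 0.015, up
  to 10,000 trees, subsample 0.5; the tree count maximizing cumulative
  out-of-bag improvement is kept. The predictive SD is the training-
  residual SD of the truncated ensemble — homoscedastic by design, since
  boosting provides no per-point variance.
* **Stacked SDMs**: one random forest per species (min leaf 5, sqrt
  feature sampling); probability = fraction of trees voting presence.
  Richness mean `sum p_i`, variance `sum p_i (1 − p_i)` (independent-
  Bernoulli sum). Species seen in only one training class get a flagged
  constant probability; species absent from training are excluded from
  the sum.
* **JSDM**: logistic model per species with shared latent factors,
  `logit p_i = alpha_i + beta_i · x + lambda_i · z`, `z ~ N(0, I)`. Fit by
  Monte-Carlo maximum marginal likelihood: the latent variable is
  integrated with K = 32 fixed standard-normal draws (common random
  numbers, softmax importance weights), optimized by L-BFGS with an
  analytic gradient; covariates are standardized internally. Each
  site-year row carries its own latent draw during fitting (a composite-
  likelihood simplification; loadings remain identifiable from the
  within-row cross-species structure). Prediction samples latent factors
  and Bernoulli detections and reports the Monte-Carlo mean and SD of
  richness. With zero loadings this reduces to the stacked formula; with
  nonzero loadings its intervals are strictly wider. This linear
  latent-factor model deliberately stands in for nonlinear
  neural-network JSDMs: it keeps the probabilistic contract (shared
  latent state inducing richness over-dispersion) while remaining
  testable against closed-form reductions.

## Evaluation

Metrics operate on Gaussian forecasts joined to observations on
(site, year): RMSE; central-interval coverage (zero-SD forecasts covered
only by exact equality); mean Gaussian deviance
`log(2 pi sd^2) + (y − mean)^2 / sd^2` with a 1e-6 variance floor, logged
when triggered; per-forecast skill differences against a baseline on
identical keys; and the MSE decomposition — per site, the squared error of
the site's mean prediction plus the mean squared error of the anomalies —
weighted by year counts so the two components add to pooled MSE exactly
(the cross term cancels within sites). Deviance and skill are reported as
per-forecast means. Horizon-stratified tables emit the same metrics per
lead year.

## The synthetic study system

The generator emulates the structure of route-level survey data without
any download: mean richness 51 with site-level spread producing an 8–91
range; a 70/21/9 (%) site/observer/residual variance split anchored at
`sigma_resid` = 3.6 species (so `sigma_site` ≈ 10.04, `sigma_obs` ≈ 5.50,
total SD 12); residual AR(1) coefficient 0.114, making lagged residuals
explain ~1.3% of residual variance; observers serving consecutive
geometric stints with mean 8 years (tenure distribution unknown in real
data; geometric is a modeling convenience), never shared across sites;
and a 0.9 per-site-year visit probability to exercise the completeness
filter. Site effects are a smooth nonlinear function of two latent
environmental gradients (weight `env_effect_scale` = 0.8) plus an
unmeasured-site term, so environmental models have recoverable but
incomplete signal — two sites with identical covariates genuinely differ.
Richness is real-valued in richness mode (Gaussian generative model) and
an integer detection count in community mode.

Community mode draws species intercepts and environmental slopes at
random; the first latent factor's loadings have positive mean 0.8 (a
shared site-suitability axis — with zero-mean loadings the cross-species
covariances cancel and richness is not over-dispersed), further factors
are zero-mean. Observer effects shift the detection logit, scaled by
`4/n_species` so the induced richness shift is of order `sigma_obs`.
Weather is a per-site seasonal sinusoid whose level and precipitation
regime follow the same two gradients, covering July of the year before
the panel starts through the following June so every survey year has a
complete window.

What the generator does not emulate — spatial autocorrelation, species
phenology, within-route stop structure, observer sharing between sites,
detection-probability variation — bounds what passing tests show: they
validate the estimators and the pipeline logic under the stated
structure, not performance on real survey data.

## Features and filters

Bioclim variables are computed over the 12 months July(y−1)–June(y)
preceding survey year y, not the calendar year. Quarters are the 10
non-wrapping 3-month windows of that sequence; ties among equally
wet/dry/warm quarters break to the earliest window (a convention — the
window definition is not standardized). BIO15 uses
`100 · SD(prec) / (1 + mean(prec))`, the (mean+1) guard keeping
zero-precipitation inputs finite. Summer NDVI averages April–June of the
survey year; winter NDVI averages December of the prior year with January
and February of the survey year. The completeness filter keeps sites with
at least `ceil(0.7 · 22) = 16` observed training years at the default
0.7 fraction; the train/test split is at year ≤ 2003 by default (22
training years, 10 test horizons). Site-level covariates are taken as
given; no spatial buffering or raster handling is attempted.

## Problem sizes and tolerances

The recovery experiments run at 300 sites × 22 training years with 500
post-warmup draws (a few seconds); the calibration experiment at 300
sites × 10 test years (~3,000 forecasts); unit tests use smaller panels
(40–150 sites) with 50–300 draws. Recovery tests use 3-combined-SE bands
(posterior SD plus generator Monte-Carlo SE); exact identities
(decomposition additivity, sqrt(h) scaling, Bernoulli-sum variance) are
asserted to 1e-9 relative or machine precision.

One calibration caveat is documented rather than hidden: the average
model's plug-in Gaussian intervals (mean and SD estimated from 22 points,
z-quantiles) have exact expected coverage
`2·T21(1.96/sqrt(1+1/22)) − 1 = 93.1%`, not 95% — the classic t-versus-z
finite-sample effect. The corresponding calibration test asserts the
nominal band and is expected to fail by ~2 points; a forecaster pooling
its residual SD across sites (as the observer-corrected average does)
does not show the shortfall.

## Known limitations

The Gibbs sampler assumes iid residuals; it is mildly misspecified under
the generator's weak AR(1), with the small absorptions quantified above.
The JSDM's composite likelihood understates cross-year dependence at a
site. The GBM's homoscedastic SD ignores covariate-dependent error scale.
Forecast archives store Gaussian summaries only, so non-Gaussian
predictive shapes (e.g. the JSDM's finite-sample richness distribution)
are summarized, not preserved.
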