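# Methods

`airsynth` estimates the causal impact of municipal winter heating on urban
air quality by coupling two stages: random-forest weather normalization of
hourly city-level pollutant series ("deweathering"), and ridge-augmented
synthetic control (ASCM) estimation on the resulting weekly series. A
synthetic panel generator with a known injected heating effect makes every
stage testable by parameter recovery. This note records the models, the
parameters that matter, the numerical choices, and what the tests do and do
not establish.

## Study design

Cities are grouped as *treated* (municipal heating, e.g. a "2+26"-style
group), *control* (southern nonheating cities, the donor pool) and
optionally *alternative* (partially heated). A *heating year* is labelled
by the calendar year its season starts in; the season runs from a start
date in October–November to 30 April of the next year. For each heating
year the pre-treatment window is 1 May → start (nonheating weeks) and the
post-treatment window is the heating season itself. Weeks are 7-day blocks
anchored to the treated group's start date so the treatment boundary is a
week boundary; intervals are half-open `[start, end)`.

Treated units are population-weighted averages over member cities
(Σ wᵢxᵢ / Σ wᵢ with wᵢ = population, renormalized over cities with data).
Completeness rules follow common regulatory practice: a daily mean needs
≥ 18 of 24 hours, a weekly mean ≥ 4 of 7 days, an 8-hour ozone window ≥ 6
of 8 hours and an MDA8 day ≥ 18 valid windows. Ox (ppbv) converts NO₂ and
O₃ from μg m⁻³ at the 25 °C / 1013 hPa reference state (÷1.88 and ÷1.96);
the reference state is a convention choice, stated here because different
agencies use 0 °C or 20 °C.

## Weather normalization

Per city and pollutant, a regression forest is trained on 9 meteorological
features (temperature, RH, wind speed/direction, pressure, boundary-layer
height, total cloud cover, surface net solar radiation, precipitation) and
5 time features (Unix-time linear trend, day of year, lunar day of year,
day of week, hour of day). The lunar day comes from a bundled Lunar New
Year table (1990–2030): exact and dependency-free; it captures
Spring-Festival emission anomalies.

Defaults: 300 trees, minimum terminal node size 5, a seeded uniform random
70/30 row split (held-out r, bias and RMSE are reported from the 30%), and
`max_features = 1/3` per split — `floor(14/3) = 4` candidate features, the
regression default (`mtry = p/3`) of the ranger/rmweather stack this
workflow mirrors. The feature subsampling matters scientifically, not just
computationally: with all 14 features available at every split, the forest
prefers temperature over day-of-year to encode the seasonal cycle (winter
straddles the day-of-year wraparound, so one temperature split is cheaper
than two calendar splits), and whatever seasonal signal rides on
temperature is then stripped by the normalization below.

The deweathered value at hour *t* averages `n_resample` (default 1000)
predictions in which the 9 meteorological features are replaced by a row
drawn uniformly with replacement from the whole observation period while
the 5 time features keep their actual values. Rows are drawn as a joint
block to preserve cross-variable structure (BLH–temperature, speed–
direction); independent per-variable draws would create unphysical states.
Missing-met hours are excluded from the pool (equivalent to redrawing).
Negative means are clipped to zero at reporting only, never inside the
average. The weather effect is observed − deweathered.

Known limitation: when meteorology is confounded with season, part of the
season-locked emission signal is attributed to meteorological features and
removed — weather normalization is only identified insofar as
meteorological states overlap across seasons. We quantified this with
twin-panel experiments (identical synthetic panels with the heating step
switched on and off; the difference of the two deweathered series isolates
the forest's rendition of the step). On a two-year panel with realistic
synoptic variability, the forest renders a 10 μg m⁻³ season-long step
fully in deep winter (weekly renditions of ~10 in January–March) but
smears it across the season boundaries by ±3–4 weeks and leaks
~1–2 μg m⁻³ into the adjacent nonheating months (the period mean is
conserved by construction of the resampling average). Net effect: the full
deweather → synthetic-control pipeline recovers ~70–80% of an injected
step under the default two-year conditions, while the estimation chain
alone is unbiased — on ground-truth non-met components recovery is exact,
and on raw observed data with 20 donors it is within ~5%. Longer training
panels decouple season from weather (different meteorology at the same
calendar day across years) and shrink the loss; a two-year window is the
hard case. Any implementation of this normalization inherits this
behaviour; it is a property of the estimand, not a solver defect.

## Ridge-augmented synthetic control

For one treated unit, pollutant and heating year, with `Y0_pre`
(controls × pre weeks), `Y0_post`, `y1_pre`:

* Simplex weights: γ minimizes ‖y1_pre − Y0_preᵀγ‖² subject to γ ≥ 0,
  Σγ = 1, plus a tie-breaking ridge 1e-8 (scaled by the Gram trace) for
  uniqueness. Solved by a primal active-set method on the KKT system —
  deterministic, exact to the stated KKT tolerance (1e-7, problem-scaled),
  with a final ridge-free polish on the support so vertex solutions are
  exact. Verified in the tests against an exhaustive 0.001-step simplex
  grid search.
* Outcome model: for each post week *s*, ridge regression across control
  units of the post outcome on centered pre outcomes,
  η_s = (X̃ᵀX̃ + λI)⁻¹X̃ᵀy_s with X̃ = Y0_pre centered by control means.
  λ is selected from 10 log-spaced values spanning 1e-3–1e3 × the mean
  centered Gram diagonal by leave-one-control-out CV of the *augmented*
  prediction. λ = 0 with a singular system falls back to the smallest
  positive grid value with a warning.
* Augmented counterfactual: cf(s) = γᵀY0_post(s) + (y1_pre − Y0_preᵀγ)ᵀη_s.
  With exact pre-fit the correction vanishes; λ→∞ recovers plain SCM. The
  pre-period counterfactual is the SCM fit path (the correction applies
  only after treatment begins). `pre_rmse_uniform` (γ = 1/n) is reported
  as the no-optimization baseline; the fitted weights can never do worse.
* No intercept is fit before weighting; level adjustment lives in the
  centered ridge stage. Missing weekly values: a control missing > 10% of
  the window's weeks is dropped, shorter gaps are linearly interpolated up
  to 2 consecutive weeks.

Uncertainty: Jackknife+ pointwise (1−α) intervals, α = 0.05. Each control
is deleted in turn and the ASCM refit (λ fixed at the full-fit value so
refits are cheap and deterministic); the interval at week *s* uses the
order statistics of cf₋ᵢ(s) ∓ Rᵢ at ranks ⌈(1−α)(n+1)⌉ (clamped to n),
where Rᵢ is the pre-period RMSE of the leave-i-out fit. Defining Rᵢ as the
pre-RMSE is a package choice: the pre-fit error is the best available
proxy for post-period counterfactual error under the design's assumption
that nonheating-week behaviour carries over. Requires ≥ 5 controls.

Inference against the sharp null uses in-place placebo tests: each control
city in turn is pretended to be treated (same calendar) and fitted against
the remaining controls; `pseudo_p = (1 + #{|placebo effect| ≥ |treated
effect|}) / (n + 1)` on heating-period mean effects.

## Effect summaries

The synthetic difference is factual − counterfactual per week.
Heating-period effect = mean over post weeks. Annual effect = (Σ post-week
effects × 7) / 365 — the effect mass spread over the year with zero
assumed outside the season, because the design identifies effects only
while heating is on (`convention="heating_period"` reports the
heating-period mean instead). Relative contribution = annual effect /
factual annual mean × 100. Multi-year "±" values are SDs across heating
years; monthly climatologies pool all years per calendar month (mean ± SD).
Trend rates are plain OLS of annual values on calendar year.

## Health burden

AF = 1 − 1/RR with the default log-linear curve
RR = exp(β·max(0, c − c₀)), β = 0.0076 per μg m⁻³ (≈ 8% excess risk per
10 μg m⁻³, a standard long-term all-cause PM2.5 slope) and threshold
c₀ = 5 μg m⁻³ (the WHO annual guideline). Deaths = AF × baseline deaths;
avoided deaths are differences between scenario years. The curve is
deliberately pluggable (`rr_curve`): published integrated exposure-response
curves can be supplied as callables; the defaults are for worked-example
arithmetic, not epidemiological authority. Baseline mortality is a
required user input.

## Synthetic panel generator

Per city, pollutant and hour:

    baseline(t) = base + trend(t) + seasonal + weekly + diel + holiday
    observed(t) = baseline(t) · m(met_t) · ε(t) + heating_step(t)

All components are returned exactly (observed = trend + seasonal + met +
heating + noise, to machine precision), so recovery tests compare against
stored truth rather than re-derived values.

* Meteorology: seasonal + diel harmonics with AR(1) anomalies (coefficient
  0.95 hourly ≈ one-day decorrelation). Temperature 14 ∓ 13 °C seasonally
  with 5 °C synoptic SD; BLH lognormal around 560 m with modest seasonal
  amplitude (±140 m) and strong synoptic variability (log-SD 0.38), lower
  at night and in winter; radiation from a clear-sky diel curve damped by
  cloud cover. The synoptic-to-seasonal variance ratios are the ones that
  make deweathering identifiable (states overlap across seasons), which is
  also the realistic regime.
* Modulation m: for primary pollutants, inverse in log-BLH and log-wind
  speed (ventilation), mild humidity and precipitation terms and a weak
  BLH×temperature interaction; for ozone, radiation- and
  temperature-driven. Normalized to unit mean over the period so the met
  component has zero period mean by construction.
* Emission components (PM2.5 scale): winter-peaked seasonality ±20 μg m⁻³,
  weekly ±2, morning-rush diel ±6, a Lunar-New-Year bump of up to
  9 μg m⁻³, and a shared linear trend (−5 μg m⁻³ yr⁻¹ by default; controls
  can be given a divergent trend to stress the estimator, since how control
  emission trends compare to treated ones is not observable).
* Noise ε: lognormal, unit mean, scale set by `noise_sd` (default 8 μg m⁻³
  at the PM2.5 base level). The heating step is added after the
  multiplicative noise, so the injected Δ (default 10 μg m⁻³ PM2.5) is the
  exact treated-minus-control contrast in expectation and positivity is
  preserved. Alternative cities receive `alternative_fraction` × Δ.
* Default panel: 20 controls, 8 treated, hourly from 1 May 2015 to
  30 April 2017 — two complete heating years starting 15 November.

What the generator does not emulate: atmospheric chemistry (no secondary
aerosol response), spatial transport between cities, met-correlated
missingness, or instrument artifacts. Passing recovery tests therefore
demonstrates the pipeline's statistical correctness under realistic
confounding, not robustness to chemistry-driven nonlinearity.

## Problem sizes in the test suite and acceptance script

Chosen so the whole suite runs on one CPU at laptop scale:

* The full-pipeline recovery fixture uses the default panel (20 controls,
  8 treated, 2 heating years, Δ = 10) with 50-tree forests and
  `n_resample = 100`. Side experiments showed 50 vs 100 vs 300 trees move
  the recovered effect by < 0.2 μg m⁻³; the forest defaults remain 300
  trees and 1000 resamples for analysis use.
* Placebo calibration (50 null + 50 effect replicates) and Jackknife+
  coverage (200 replicates) run at the ASCM layer on idealized
  weather-normalized inputs: the generator's non-met components plus
  0.8 μg m⁻³ weekly residual noise per unit, with the treated unit an
  8-city average as in the design. These suites test the inference layer's
  calibration; the forest path is exercised end to end by the recovery
  fixture.
* MDA8 is validated against an exhaustive window-enumeration oracle on
  1000 random gap-ridden days; SCM weights against a 0.001-step simplex
  grid; the ridge stage against independent closed-form solves.

## Degenerate inputs and tie-breaks

Constant targets return r = 0 with a warning (model still returned);
all-identical controls give zero-width Jackknife+ intervals; a zero
baseline rejects percent change; fewer than 5 controls refuse intervals
and placebo scans; fewer than 3 annual values refuse trend fits. Ties in
the λ grid resolve to the first (smallest) minimizer. All randomness flows
from explicit seeds; identical configuration and seed reproduce every
artifact byte for byte.
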