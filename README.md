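# airsynth

Causal estimation of winter-heating impacts on urban air quality, combining
machine-learning weather normalization with ridge-augmented synthetic
control (ASCM), plus a synthetic multi-city panel generator that makes the
whole pipeline testable by parameter recovery.

## The problem

Municipal winter heating in northern China switches on across entire
regions on known calendar dates, creating a quasi-natural experiment: how
much does heating raise PM2.5, SO₂, CO and ozone, and how much have clean
heating policies reduced that impact? Two confounders make the naive
heating-vs-nonheating comparison invalid: meteorology (winter stagnation
raises concentrations with or without heating) and diverging emission
trends between northern and southern cities. This package implements the
two-step design that addresses both, for epidemiologists and atmospheric
scientists who want to apply or stress-test it:

1. **Weather normalization** — a random forest per city and pollutant
   learns concentration as a function of 9 meteorological and 5 time
   features; the *deweathered* concentration at hour *t* averages the
   model's predictions over `n_resample` meteorology rows drawn from the
   whole observation period with the time features held fixed, removing
   weather-driven variability.
2. **Augmented synthetic control** — for each treated unit (a
   population-weighted city group) and heating year, simplex weights γ
   (γ ≥ 0, Σγ = 1) reproduce the unit's deweathered pre-treatment weekly
   trajectory from nonheating donor cities, and a cross-unit ridge
   regression corrects the estimate for residual pre-treatment imbalance:

   ```
   cf(s) = γᵀ Y0_post(s) + (y1_pre − Y0_preᵀ γ)ᵀ η_s,
   η_s  = (X̃ᵀX̃ + λI)⁻¹ X̃ᵀ y_s,   X̃ = Y0_pre centered over controls
   ```

   The *synthetic difference* (factual − counterfactual) over heating
   weeks is the causal heating impact. Pointwise 95% bands come from the
   Jackknife+ leave-one-control-out procedure, and in-place placebo tests
   (every control pretended treated in turn) give a rank-based pseudo
   p-value. Effects are summarized into heating-period means, annualized
   effects, relative contributions, trend rates and PM2.5-attributable
   mortality under a pluggable exposure-response.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Simulate the default panel — 20 nonheating control cities and 8 treated
cities whose PM2.5 steps up by exactly 10 μg m⁻³ during each
mid-November → April heating season — and estimate the heating impact per
heating year with the synthetic-control layer:

```python
import pandas as pd
import airsynth as ax
from airsynth.pipeline import heating_year_design, fit_heating_year

cfg = ax.PanelConfig(pollutants=("pm25",), seed=1)
panel, truth, calendar, groups = ax.generate_panel(cfg)

wide = panel.pivot(index="timestamp", columns="city_id", values="pm25")
for year in (2015, 2016):
    design = heating_year_design(wide, calendar, groups, year)
    est, effect = fit_heating_year(design, unit="two_plus_26", pollutant="pm25")
    factual = float(pd.concat([design["y1_pre"], design["y1_post"]]).mean())
    summary = ax.summarize(effect, factual_annual_mean=factual)
    print(f"heating year {year}:")
    print(f"  pre-fit RMSE   : {est.pre_rmse_:.2f} ug/m3 "
          f"(uniform weights: {est.pre_rmse_uniform_:.2f})")
    print(f"  heating effect : {effect.post_effect().mean():.2f} ug/m3 (injected: 10.00)")
    print(f"  annual effect  : {summary.annual_effect:.2f} ug/m3 "
          f"({summary.relative_contribution:.1f}% of the annual mean)")

placebo = ax.placebo_scan(design["Y0_pre"], design["Y0_post"],
                          design["y1_pre"], design["y1_post"])
print(f"placebo pseudo-p : {placebo.pseudo_p:.3f} "
      f"(minimum possible: {1/(len(placebo.placebo_mean_effects)+1):.3f})")
```

prints

```
heating year 2015:
  pre-fit RMSE   : 1.50 ug/m3 (uniform weights: 2.58)
  heating effect : 7.88 ug/m3 (injected: 10.00)
  annual effect  : 3.63 ug/m3 (6.3% of the annual mean)
heating year 2016:
  pre-fit RMSE   : 2.10 ug/m3 (uniform weights: 3.46)
  heating effect : 7.94 ug/m3 (injected: 10.00)
  annual effect  : 3.50 ug/m3 (6.7% of the annual mean)
placebo pseudo-p : 0.048 (minimum possible: 0.048)
```

Reading the output: the fitted simplex weights match the treated group's
nonheating weeks much better than uniform donor weights (RMSE 1.50 vs
2.58); the heating-period effect lands near the injected 10 μg m⁻³ — this
quick example runs on *observed* concentrations, so per-city weather noise
moves the estimate by 1–2 μg m⁻³, the variability that the deweathering
stage exists to remove; spread over the whole year the effect is
~3.6 μg m⁻³, about 6% of the annual mean; and the treated unit's effect
is larger in magnitude than every in-place placebo, giving the smallest
achievable pseudo p-value.

The full pipeline, including the random-forest deweathering stage and the
health-burden layer, is driven either from Python (`airsynth.pipeline`) or
the CLI:

```
airsynth example-config > config.yaml
airsynth run --config config.yaml --seed 1
```

which writes per-stage artifacts (deweathered series, weekly design
matrices, ASCM fits with Jackknife+ bands, effect summaries, attributable
deaths) plus a manifest with checksums into the configured run directory.

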