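"""Shared fixtures.

The expensive session fixtures simulate panels once and are reused across
test modules; sizes are chosen so the whole suite stays well inside a
laptop-scale run while the full-pipeline fixture matches the package's
default parameter-recovery conditions (20 controls, 8 treated, 2 heating
years, a 10 μg m⁻³ PM2.5 heating step, 100 meteorological resamples).
"""

from __future__ import annotations

import dataclasses
import datetime as dt


import pandas as pd
import pytest

import airsynth as ax
from airsynth.pipeline import fit_heating_year, heating_year_design


@pytest.fixture(scope="session")
def small_panel():
    """One-heating-year panel: 10 controls, 3 treated, 1 alternative."""
    cfg = ax.PanelConfig(
        n_control=10,
        n_treated=3,
        n_alternative=1,
        end=dt.date(2016, 4, 30),
        pollutants=("pm25",),
        seed=42,
    )
    return cfg, *ax.generate_panel(cfg)


@pytest.fixture(scope="session")
def rf_city(small_panel):
    """A fitted WeatherNormalizer for one treated city of the small panel."""
    cfg, panel, truth, calendar, groups = small_panel
    sub = panel[panel["city_id"] == "T00"].sort_values("timestamp")
    feats = ax.build_features(sub)
    target = pd.Series(sub["pm25"].to_numpy(), index=feats.index)
    model, metrics = ax.train_rf(
        feats, target, ax.RfConfig(n_tree=40, n_resample=100, seed=7)
    )
    dew = model.deweather(feats)
    return {
        "features": feats,
        "target": target,
        "model": model,
        "metrics": metrics,
        "deweathered": dew,
        "truth": truth,
        "calendar": calendar,
    }


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at the default recovery conditions (the heavy fixture).

    Panel: 20 controls, 8 treated, 2 heating years, Δ=10 μg m⁻³ PM2.5.
    Deweathering: 50-tree forests, 100 meteorological resamples per hour.
    Returns the per-year ASCM fits on deweathered weekly data plus the
    forest metrics and the ground truth.
    """
    cfg = ax.PanelConfig(
        n_control=20,
        n_treated=8,
        pollutants=("pm25",),
        heating_effect={"pm25": 10.0},
        seed=123,
    )
    panel, truth, calendar, groups = ax.generate_panel(cfg)
    rf = ax.RfConfig(n_tree=50, n_resample=100, seed=1)
    dews, metrics = {}, {}
    for i, (city, sub) in enumerate(panel.groupby("city_id")):
        sub = sub.sort_values("timestamp")
        feats = ax.build_features(sub)
        target = pd.Series(sub["pm25"].to_numpy(), index=feats.index)
        model, m = ax.train_rf(
            feats, target, dataclasses.replace(rf, seed=1000 + i)
        )
        dews[city] = model.deweather(feats)
        metrics[city] = m
    wide = pd.DataFrame(dews)
    fits, effects, designs = {}, {}, {}
    for year in (2015, 2016):
        d = heating_year_design(wide, calendar, groups, year)
        est, eff = fit_heating_year(d, unit="two_plus_26", pollutant="pm25")
        designs[year], fits[year], effects[year] = d, est, eff
    return {
        "config": cfg,
        "panel": panel,
        "truth": truth,
        "calendar": calendar,
        "groups": groups,
        "deweathered": wide,
        "metrics": metrics,
        "designs": designs,
        "fits": fits,
        "effects": effects,
    }
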