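"""Summaries of synthetic-control effects: annual, monthly, trends, changes.

The *synthetic difference* is the factual minus counterfactual weekly
concentration after the heating switch-on — the causal heating impact in
concentration units. This module aggregates weekly synthetic differences
into the quantities reported in heating-impact studies:

* heating-period effect — mean weekly effect over the post weeks;
* annual effect — the heating-period effect mass spread over a full year
  (the design identifies effects only while heating is on, so weeks outside
  the season contribute zero);
* relative contribution — annual effect as a percent of the factual annual
  mean concentration;
* monthly climatology — calendar-month means +/- SD pooled across years;
* interannual trend rates via ordinary least squares.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ascm import AscmFit

__all__ = [
    "EffectSeries",
    "EffectSummary",
    "TrendFit",
    "synthetic_difference",
    "summarize",
    "multi_year_summary",
    "trend_rate",
    "percent_change",
    "share_of_decline",
]

DAYS_PER_YEAR = 365.0


@dataclass
class EffectSeries:
    """Weekly synthetic differences for one unit/pollutant/heating year.

    ``effect`` spans pre + post weeks (pre-week effects should hover near
    zero in a good fit and are kept for diagnostics); ``post_start`` marks
    the heating switch-on. CI bands, when present, are the fit's
    counterfactual bands transformed to the effect scale.
    """

    unit: str
    pollutant: str
    heating_year: int
    effect: pd.Series
    post_start: pd.Timestamp
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None

    def post_effect(self) -> pd.Series:
        return self.effect[self.effect.index >= self.post_start]

    def pre_effect(self) -> pd.Series:
        return self.effect[self.effect.index < self.post_start]


@dataclass
class EffectSummary:
    """Per-heating-year scalar summaries of an effect series."""

    unit: str
    pollutant: str
    heating_year: int
    heating_period_effect: float
    annual_effect: float
    factual_annual_mean: float
    counterfactual_annual_mean: float
    relative_contribution: float  # percent of the factual annual mean
    n_post_weeks: int
    monthly_effects: dict[int, float] = field(default_factory=dict)


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r2: float


def synthetic_difference(
    factual: pd.Series,
    fit: AscmFit,
    unit: str = "",
    pollutant: str = "",
    heating_year: int = 0,
    post_start: pd.Timestamp | None = None,
) -> EffectSeries:
    """Factual minus counterfactual weekly series, with transformed bands.

    The counterfactual's confidence band ``[lo, hi]`` maps to the effect
    band ``[factual - hi, factual - lo]``.
    """
    cf = fit.counterfactual
    if len(factual) != len(cf) or not factual.index.equals(cf.index):
        raise ValueError("factual series and counterfactual are misaligned")
    effect = factual - cf
    lo = hi = None
    if fit.ci_lower is not None:
        post_fact = factual.loc[fit.ci_lower.index]
        lo = post_fact - fit.ci_upper
        hi = post_fact - fit.ci_lower
    if post_start is None:
        if fit.ci_lower is None:
            raise ValueError("post_start required when the fit carries no bands")
        post_start = fit.ci_lower.index[0]
    return EffectSeries(
        unit=unit,
        pollutant=pollutant,
        heating_year=heating_year,
        effect=effect,
        post_start=pd.Timestamp(post_start),
        ci_lower=lo,
        ci_upper=hi,
    )


def summarize(
    effects: EffectSeries,
    factual_annual_mean: float,
    convention: str = "annual",
) -> EffectSummary:
    """Scalar summaries of one heating year's effect series.

    ``annual_effect`` spreads the post-week effect mass over 365 days
    (``convention="annual"``) or equals the heating-period mean
    (``convention="heating_period"``). The relative contribution is the
    annual effect as a percent of the factual annual mean, and the
    counterfactual annual mean is the factual mean minus the annual effect.
    """
    if convention not in ("annual", "heating_period"):
        raise ValueError(f"unknown convention {convention!r}")
    post = effects.post_effect().dropna()
    if post.empty:
        raise ValueError("effect series has no post (heating) weeks")
    heating_mean = float(post.mean())
    annual = float(post.sum() * 7.0 / DAYS_PER_YEAR)
    headline = annual if convention == "annual" else heating_mean
    monthly = post.groupby(post.index.month).mean().to_dict()
    rel = (
        100.0 * headline / factual_annual_mean
        if factual_annual_mean != 0
        else float("nan")
    )
    return EffectSummary(
        unit=effects.unit,
        pollutant=effects.pollutant,
        heating_year=effects.heating_year,
        heating_period_effect=heating_mean,
        annual_effect=headline,
        factual_annual_mean=float(factual_annual_mean),
        counterfactual_annual_mean=float(factual_annual_mean) - headline,
        relative_contribution=rel,
        n_post_weeks=int(post.size),
        monthly_effects={int(k): float(v) for k, v in monthly.items()},
    )


def multi_year_summary(summaries: list[EffectSummary]) -> dict:
    """Mean +/- SD of annual effects across heating years, plus the change.

    The spread is the population SD across years (ddof=0 is used when only
    one year exists; ddof=1 otherwise, matching how multi-year +/- values
    are conventionally reported).
    """
    if not summaries:
        raise ValueError("no summaries given")
    years = [s.heating_year for s in summaries]
    vals = np.array([s.annual_effect for s in summaries], float)
    rels = np.array([s.relative_contribution for s in summaries], float)
    first, last = vals[np.argmin(years)], vals[np.argmax(years)]
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out = {
        "mean": float(vals.mean()),
        "sd": sd,
        "relative_mean": float(np.nanmean(rels)),
        "relative_sd": float(np.nanstd(rels, ddof=1)) if len(rels) > 1 else 0.0,
        "first_year": int(min(years)),
        "last_year": int(max(years)),
        "change": float(last - first),
    }
    out["percent_change"] = (
        100.0 * (last - first) / first if first != 0 else float("nan")
    )
    return out


def monthly_climatology(series_by_year: list[EffectSeries]) -> pd.DataFrame:
    """Calendar-month mean +/- SD of weekly effects pooled across years."""
    frames = []
    for es in series_by_year:
        post = es.post_effect().dropna()
        frames.append(pd.DataFrame({"month": post.index.month, "effect": post.to_numpy()}))
    pooled = pd.concat(frames, ignore_index=True)
    g = pooled.groupby("month")["effect"]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})


def trend_rate(annual_values: dict[int, float] | pd.Series) -> TrendFit:
    """OLS trend of annual values on calendar year (units yr^-1)."""
    s = pd.Series(annual_values).dropna().sort_index()
    if len(s) < 3:
        raise ValueError("trend needs >= 3 annual values")
    years = s.index.to_numpy(float)
    vals = s.to_numpy(float)
    if np.allclose(vals, vals[0]):
        return TrendFit(slope=0.0, intercept=float(vals[0]), r2=0.0)
    res = stats.linregress(years, vals)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def percent_change(a: float, b: float) -> tuple[float, float]:
    """Absolute and percent change from baseline ``a`` to endpoint ``b``."""
    if a == 0:
        raise ValueError("baseline value must be nonzero")
    return b - a, 100.0 * (b - a) / a


def share_of_decline(
    effect_start: float, effect_end: float, total_start: float, total_end: float
) -> float:
    """Percent of a total concentration decline explained by an effect decline.

    ``100 * (effect_start - effect_end) / (total_start - total_end)`` — e.g.
    the share of a city's total PM2.5 improvement attributable to the
    shrinking heating impact.
    """
    denom = total_start - total_end
    if denom == 0:
        raise ValueError("total concentrations did not change")
    return 100.0 * (effect_start - effect_end) / denom
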