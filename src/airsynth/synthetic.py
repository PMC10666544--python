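"""Synthetic multi-city hourly panels with a known heating effect.

The generator emulates the structure of Chinese national air-quality panels
used to study municipal winter heating: a control group of southern cities
with no heating season, a treated group whose concentrations step up by a
known amount during the heating season, and optional "alternative" cities
that receive a stated fraction of that step. Every generated concentration
decomposes exactly into trend + seasonal + meteorological + heating + noise
components, which are returned alongside the panel so the full
deweather -> synthetic-control pipeline can be validated by parameter
recovery.

Model
-----
For each city ``i``, pollutant ``p`` and hour ``t``::

    baseline(t) = base_p + trend(t) + seasonal(t) + weekly(t) + diel(t) + holiday(t)
    observed(t) = baseline(t) * m(met_t) * eps(t) + heating_step(t)

``m`` is a smooth positive function of the city's meteorology (inverse in
boundary-layer height and wind speed, modulated by temperature and humidity
for the primary pollutants; driven by radiation and temperature for ozone),
normalized to unit mean over the simulated period. ``eps`` is lognormal with
unit mean, so the heating step equals the treated-minus-control contrast in
expectation. Meteorology itself is seasonal + diel harmonics plus AR(1)
noise (coefficient 0.95, about one day of persistence at hourly steps).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import GroupSpec, HeatingCalendar, aggregate_weekly, population_weighted
from .lunar import LUNAR_NEW_YEAR

__all__ = ["PanelConfig", "GroundTruth", "generate_panel", "true_weekly_effect"]

POLLUTANTS = ("pm25", "so2", "no2", "co", "o3")
MET_VARS = ("temp", "rh", "ws", "wd", "pressure", "blh", "tcc", "ssr", "tp")

# per-pollutant mean levels (μg m⁻³; CO mg m⁻³) and component amplitudes,
# loosely matched to mid-2010s urban China
_BASE = {"pm25": 55.0, "so2": 25.0, "no2": 35.0, "co": 1.0, "o3": 60.0}
# winter-peaked emission seasonality (industrial activity, shallow regional
# burning), separate from the heating step and the meteorological modulation
_SEASONAL_AMP = {"pm25": 20.0, "so2": 9.0, "no2": 10.0, "co": 0.30, "o3": -18.0}
_DIEL_AMP = {"pm25": 6.0, "so2": 3.0, "no2": 7.0, "co": 0.12, "o3": -14.0}
_WEEKLY_AMP = {"pm25": 2.0, "so2": 1.0, "no2": 2.5, "co": 0.05, "o3": -1.5}
_HOLIDAY_AMP = {"pm25": 9.0, "so2": 3.0, "no2": -4.0, "co": 0.08, "o3": 2.0}
_AR1 = 0.95


@dataclass
class PanelConfig:
    """Configuration of one synthetic panel.

    Parameters
    ----------
    n_control, n_treated, n_alternative : int
        City counts per group. The control group needs >= 2 members for
        synthetic-control fitting.
    start, end : datetime.date
        Simulated period, hourly, inclusive of ``end``'s 24 hours. The
        default two full May-April heating years support year-by-year fits.
    heating_effect : dict
        Additive concentration step (μg m⁻³; CO mg m⁻³) applied in treated
        cities during heating hours.
    alternative_fraction : float in (0, 1)
        Fraction of the step applied in alternative cities.
    met_effect_scale : float
        Scales the log of the meteorological modulation; 0 switches
        meteorology's influence on concentrations off.
    trend_slope : float
        Linear PM2.5 emission trend in μg m⁻³ yr⁻¹ (other pollutants scaled
        by their base level), shared by all groups.
    control_trend_offset : float
        Extra slope (same units) added to control cities only, to stress
        divergent emission trends between donor pool and treated group.
    noise_sd : float
        Approximate PM2.5 noise SD in μg m⁻³; internally converted to the
        lognormal scale relative to the base level and shared (relatively)
        by all pollutants.
    heating_start : (month, day)
        Heating switch-on within Oct-Nov of each label year.
    heating_start_jitter_days : int
        Max per-city backward jitter of the start date (deterministic from
        the seed).
    min_heating_years : int
        Complete heating seasons the period must contain; fewer raises.
    """

    n_control: int = 20
    n_treated: int = 8
    n_alternative: int = 0
    start: _dt.date = _dt.date(2015, 5, 1)
    end: _dt.date = _dt.date(2017, 4, 30)
    heating_effect: dict[str, float] = field(
        default_factory=lambda: {"pm25": 10.0, "so2": 5.0, "no2": 0.0, "co": 0.14, "o3": 5.0}
    )
    alternative_fraction: float = 0.4
    met_effect_scale: float = 1.0
    trend_slope: float = -5.0
    control_trend_offset: float = 0.0
    noise_sd: float = 8.0
    seed: int = 0
    populations: dict[str, float] | None = None
    pollutants: tuple[str, ...] = POLLUTANTS
    heating_start: tuple[int, int] = (11, 15)
    heating_start_jitter_days: int = 0
    min_heating_years: int = 1

    def __post_init__(self) -> None:
        if self.n_control < 2:
            raise ValueError("need >= 2 control cities")
        if self.n_treated < 1 or self.n_alternative < 0:
            raise ValueError("city counts must be >= 1 treated, >= 0 alternative")
        if self.start >= self.end:
            raise ValueError("start must precede end")
        if not 0 < self.alternative_fraction < 1:
            raise ValueError("alternative_fraction must lie in (0, 1)")
        unknown = set(self.pollutants) - set(POLLUTANTS)
        if unknown:
            raise ValueError(f"unknown pollutants {sorted(unknown)}")
        for p, v in self.heating_effect.items():
            if v < 0:
                raise ValueError(f"heating_effect[{p}] must be >= 0")
        if self.populations is not None:
            for c, pop in self.populations.items():
                if not pop > 0:
                    raise ValueError(f"population of {c} must be > 0")
        month, _ = self.heating_start
        if month not in (10, 11):
            raise ValueError("heating must start in October or November")

    def city_ids(self) -> dict[str, list[str]]:
        return {
            "treated": [f"T{i:02d}" for i in range(self.n_treated)],
            "control": [f"C{i:02d}" for i in range(self.n_control)],
            "alternative": [f"A{i:02d}" for i in range(self.n_alternative)],
        }

    def heating_years(self) -> list[int]:
        """Label years whose full Oct/Nov -> 30 April season fits the period."""
        years = []
        for y in range(self.start.year, self.end.year + 1):
            latest_start = _dt.date(y, self.heating_start[0], self.heating_start[1])
            if latest_start >= self.start and _dt.date(y + 1, 4, 30) <= self.end:
                years.append(y)
        return years


@dataclass
class GroundTruth:
    """Exact per-hour component decomposition of a generated panel.

    ``components`` is a long table (city_id, timestamp, pollutant, trend,
    seasonal, met, heating, noise) whose five component columns sum exactly
    to the observed concentration. ``groups`` carries memberships and
    populations so group-level truths can be formed without the config.
    """

    components: pd.DataFrame
    groups: GroupSpec

    def observed(self) -> pd.Series:
        c = self.components
        return c["trend"] + c["seasonal"] + c["met"] + c["heating"] + c["noise"]


def _season(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float = _AR1) -> np.ndarray:
    innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -rho], innov)


def _simulate_met(rng: np.random.Generator, index: pd.DatetimeIndex) -> pd.DataFrame:
    """Seasonal + diel harmonics with AR(1) anomalies for the 9 met fields."""
    n = len(index)
    doy = index.dayofyear.to_numpy().astype(float)
    hour = index.hour.to_numpy().astype(float)
    s_winter = _season(doy, 15.0)   # +1 mid-January
    s_summer = _season(doy, 196.0)  # +1 mid-July
    diel = np.cos(2 * np.pi * (hour - 15.0) / 24.0)  # afternoon peak

    temp = 14.0 - 13.0 * s_winter + 4.0 * diel + _ar1(rng, n, 5.0)
    rh = np.clip(62.0 + 10.0 * s_summer - 8.0 * diel + _ar1(rng, n, 9.0), 5.0, 100.0)
    ws = np.maximum(0.2, 3.0 + 0.5 * _season(doy, 105.0) + _ar1(rng, n, 1.3))
    wd = np.mod(190.0 + 55.0 * s_winter + _ar1(rng, n, 60.0), 360.0)
    pressure = 1013.0 + 9.0 * s_winter + _ar1(rng, n, 4.0)
    # ventilation: modest seasonal cycle, strong synoptic variability
    blh = np.maximum(
        40.0,
        (560.0 + 140.0 * s_summer + 420.0 * np.maximum(0.0, diel))
        * np.exp(_ar1(rng, n, 0.38)),
    )
    tcc = 1.0 / (1.0 + np.exp(-(0.2 + 0.5 * s_summer + _ar1(rng, n, 1.0))))
    sun = np.maximum(0.0, np.cos(2 * np.pi * (hour - 12.0) / 24.0))
    ssr = np.maximum(0.0, sun * (0.55 + 0.45 * s_summer)) * 3.2e6 * (1 - 0.72 * tcc)
    rain_latent = _ar1(rng, n, 1.0) + 0.5 * s_summer
    tp = np.where(rain_latent > 1.6, np.expm1(np.minimum(rain_latent - 1.6, 3.0)), 0.0)

    return pd.DataFrame(
        {"temp": temp, "rh": rh, "ws": ws, "wd": wd, "pressure": pressure,
         "blh": blh, "tcc": tcc, "ssr": ssr, "tp": tp},
        index=index,
    )


def _met_log_modulation(met: pd.DataFrame, pollutant: str) -> np.ndarray:
    """Log of the meteorological multiplier before scaling/normalization."""
    if pollutant == "o3":
        return (
            0.014 * (met["temp"].to_numpy() - 14.0)
            + 0.22 * (met["ssr"].to_numpy() / 2.0e6)
            - 0.005 * (met["rh"].to_numpy() - 62.0)
            + 0.10 * np.log(met["blh"].to_numpy() / 500.0)
        )
    g = (
        -0.60 * np.log(met["blh"].to_numpy() / 500.0)
        - 0.40 * np.log((met["ws"].to_numpy() + 0.5) / 3.5)
        + 0.004 * (met["rh"].to_numpy() - 62.0)
        - 0.012 * np.log(met["blh"].to_numpy() / 500.0) * (met["temp"].to_numpy() - 14.0) / 10.0
        - 0.04 * np.minimum(met["tp"].to_numpy(), 5.0)
    )
    return g


def _holiday_profile(index: pd.DatetimeIndex) -> np.ndarray:
    """Smooth bump over the 15 days around each Lunar New Year."""
    days = index.normalize()
    bump = np.zeros(len(index))
    for year in np.unique(index.year):
        for y in (int(year) - 1, int(year)):
            if y not in LUNAR_NEW_YEAR:
                continue
            lny = pd.Timestamp(LUNAR_NEW_YEAR[y])
            offset = (days - lny).days.to_numpy()
            in_window = np.abs(offset) <= 7
            bump = np.where(
                in_window, np.cos(np.pi * offset / 7.0) * 0.5 + 0.5, bump
            )
    return bump


def default_calendar(config: PanelConfig) -> HeatingCalendar:
    """Heating calendar for treated + alternative cities of a config."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    ids = config.city_ids()
    entries = {}
    month, day = config.heating_start
    for city in ids["treated"] + ids["alternative"]:
        jitter = (
            int(rng.integers(0, config.heating_start_jitter_days + 1))
            if config.heating_start_jitter_days
            else 0
        )
        for year in config.heating_years():
            start = _dt.date(year, month, day) - _dt.timedelta(days=jitter)
            entries[(city, year)] = (start, _dt.date(year + 1, 4, 30))
    return HeatingCalendar(entries)


def generate_panel(
    config: PanelConfig,
) -> tuple[pd.DataFrame, GroundTruth, HeatingCalendar, GroupSpec]:
    """Simulate an hourly panel and its exact component decomposition.

    Returns
    -------
    panel : pd.DataFrame
        Columns ``city_id, timestamp``, one column per requested pollutant
        and the nine meteorological fields.
    truth : GroundTruth
        Long component table; ``trend+seasonal+met+heating+noise`` equals the
        panel concentration at every hour, exactly.
    calendar : HeatingCalendar
    groups : GroupSpec
    """
    if len(config.heating_years()) < config.min_heating_years:
        raise ValueError(
            f"period {config.start}..{config.end} contains "
            f"{len(config.heating_years())} complete heating seasons, "
            f"need >= {config.min_heating_years}"
        )
    ids = config.city_ids()
    all_cities = ids["treated"] + ids["control"] + ids["alternative"]
    role = {c: g for g, cs in ids.items() for c in cs}

    pop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    if config.populations is None:
        populations = {
            c: float(np.round(pop_rng.lognormal(np.log(3.0e6), 0.4)))
            for c in all_cities
        }
    else:
        populations = dict(config.populations)
        missing = [c for c in all_cities if c not in populations]
        if missing:
            raise ValueError(f"populations missing for {missing}")

    calendar = default_calendar(config)
    groups = GroupSpec(
        groups={
            "two_plus_26": ids["treated"],
            "nonheating": ids["control"],
            "alternative": ids["alternative"],
        },
        populations=populations,
    )

    index = pd.date_range(
        pd.Timestamp(config.start),
        pd.Timestamp(config.end) + pd.Timedelta(hours=23),
        freq="h",
    )
    n = len(index)
    doy = index.dayofyear.to_numpy().astype(float)
    hour = index.hour.to_numpy().astype(float)
    dow = index.dayofweek.to_numpy().astype(float)
    years_elapsed = (index - index[0]).total_seconds().to_numpy() / (365.25 * 86400.0)
    holiday = _holiday_profile(index)
    s_winter = _season(doy, 15.0)
    diel_am = np.cos(2 * np.pi * (hour - 8.0) / 24.0)  # morning-rush peak
    weekly_shape = np.cos(2 * np.pi * (dow - 2.0) / 7.0)  # midweek peak

    sigma_rel = config.noise_sd / _BASE["pm25"]
    panel_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    for ci, city in enumerate(all_cities):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, ci]))
        met = _simulate_met(rng, index)
        heating_mask = calendar.is_heating(city, index).astype(float)
        if role[city] == "control":
            step_scale = 0.0
        elif role[city] == "alternative":
            step_scale = config.alternative_fraction
        else:
            step_scale = 1.0
        city_level = float(rng.normal(1.0, 0.06))  # persistent level offsets

        frame = {"city_id": city, "timestamp": index}
        truths = []
        for p in config.pollutants:
            base = _BASE[p] * city_level
            slope = config.trend_slope * _BASE[p] / _BASE["pm25"]
            if role[city] == "control":
                slope += config.control_trend_offset * _BASE[p] / _BASE["pm25"]
            trend_c = base + slope * years_elapsed
            seasonal_c = (
                _SEASONAL_AMP[p] * s_winter
                + _WEEKLY_AMP[p] * weekly_shape
                + _DIEL_AMP[p] * diel_am
                + _HOLIDAY_AMP[p] * holiday
            )
            baseline = trend_c + seasonal_c
            if baseline.min() <= 0:
                raise ValueError(
                    f"{city}/{p}: baseline becomes non-positive; reduce "
                    "amplitudes or trend"
                )
            g = _met_log_modulation(met, p) * config.met_effect_scale
            mult = np.exp(g)
            mult /= mult.mean()  # unit-mean modulation over the period
            sig = sigma_rel  # relative noise scale shared across pollutants
            eps = np.exp(rng.normal(-0.5 * sig**2, sig, size=n)) if sig > 0 else np.ones(n)
            step = config.heating_effect.get(p, 0.0) * step_scale * heating_mask

            met_c = baseline * (mult - 1.0)
            noise_c = baseline * mult * (eps - 1.0)
            observed = trend_c + seasonal_c + met_c + step + noise_c
            frame[p] = observed
            truths.append(
                pd.DataFrame(
                    {
                        "city_id": city,
                        "timestamp": index,
                        "pollutant": p,
                        "trend": trend_c,
                        "seasonal": seasonal_c,
                        "met": met_c,
                        "heating": step,
                        "noise": noise_c,
                    }
                )
            )
        for v in MET_VARS:
            frame[v] = met[v].to_numpy()
        panel_frames.append(pd.DataFrame(frame))
        truth_frames.append(pd.concat(truths, ignore_index=True))

    panel = pd.concat(panel_frames, ignore_index=True)
    truth = GroundTruth(pd.concat(truth_frames, ignore_index=True), groups)
    return panel, truth, calendar, groups


def true_weekly_effect(
    truth: GroundTruth,
    calendar: HeatingCalendar,
    group: str = "two_plus_26",
    pollutant: str = "pm25",
) -> pd.Series:
    """Population-weighted weekly mean of the injected heating component.

    Weeks are anchored to the group's heating start of each covered heating
    year (the same anchoring the estimation pipeline uses); hours outside
    every heating period contribute zero, so a week straddling a season
    boundary takes a time-weighted intermediate value.
    """
    cities = truth.groups.members(group)
    comp = truth.components
    sub = comp[(comp["pollutant"] == pollutant) & comp["city_id"].isin(cities)]
    if sub.empty:
        raise ValueError(f"no ground truth for group {group!r} / {pollutant!r}")
    wide = sub.pivot(index="timestamp", columns="city_id", values="heating")
    hourly = population_weighted(wide, truth.groups.populations)
    daily = hourly.groupby(hourly.index.normalize()).mean()
    pieces = []
    for year in calendar.years():
        anchor = calendar.group_start(cities, year)
        lo = pd.Timestamp(_dt.date(year, 5, 1))
        # reach 6 days past the season end so a week straddling 30 April is
        # complete (time-weighted) rather than dropped as a partial block
        hi = pd.Timestamp(_dt.date(year + 1, 4, 30)) + pd.Timedelta(days=6)
        window = daily[(daily.index >= lo) & (daily.index <= hi)]
        if not window.empty:
            pieces.append(aggregate_weekly(window, anchor))
    if not pieces:
        raise ValueError("calendar has no heating year inside the panel period")
    return pd.concat(pieces)
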