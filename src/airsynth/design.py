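"""Experimental design utilities for heating-impact panels.

This module turns hourly city-level series into the objects the synthetic
control stage consumes: daily and weekly aggregates with completeness rules,
MDA8 ozone, total oxidant Ox, population-weighted group series, per-city
heating calendars, and the pre/post split of each heating year.

Conventions
-----------
* A *heating year* is labelled by the calendar year its heating season
  starts in; the season runs from a start date in October-November to
  30 April of the following year. The pre-treatment window of heating year
  ``Y`` runs from 1 May of ``Y`` (end of the previous season) to the start
  date.
* Weeks are consecutive 7-day blocks anchored to the heating start date
  (counted backward through the pre window and forward through the post
  window), so the treatment boundary coincides with a week boundary.
* Intervals are half-open ``[start, end)`` in the panel's local clock.
* Completeness: a daily mean needs >= 18 of 24 hours, a weekly mean >= 4 of
  7 days, an 8-hour ozone window >= 6 of 8 hours and an MDA8 day >= 18 valid
  windows. These follow common regulatory practice.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HeatingCalendar",
    "GroupSpec",
    "compute_mda8",
    "compute_ox",
    "aggregate_daily",
    "aggregate_weekly",
    "population_weighted",
    "split_periods",
]

# molar-mass based μg m⁻³ -> ppb conversion factors at 25 °C, 1013 hPa
_NO2_UG_PER_PPB = 1.88
_O3_UG_PER_PPB = 1.96

MIN_HOURS_PER_DAY = 18
MIN_DAYS_PER_WEEK = 4
MIN_HOURS_PER_MDA8_WINDOW = 6
MIN_WINDOWS_PER_MDA8_DAY = 18


@dataclass(frozen=True)
class HeatingCalendar:
    """Per-city heating season dates keyed by (city_id, heating_year label).

    ``entries[(city, year)] = (start_date, end_date)`` with the start in
    Oct-Nov of ``year`` and the end on 30 April of ``year + 1``.
    """

    entries: dict[tuple[str, int], tuple[_dt.date, _dt.date]]

    def __post_init__(self) -> None:
        for (city, year), (start, end) in self.entries.items():
            if start >= end:
                raise ValueError(f"{city}/{year}: start {start} !< end {end}")
            if start.year != year:
                raise ValueError(f"{city}/{year}: start {start} not in label year")

    def cities(self) -> list[str]:
        return sorted({c for c, _ in self.entries})

    def years(self, city: str | None = None) -> list[int]:
        if city is None:
            return sorted({y for _, y in self.entries})
        return sorted(y for c, y in self.entries if c == city)

    def start(self, city: str, year: int) -> _dt.date:
        return self.entries[(city, year)][0]

    def end(self, city: str, year: int) -> _dt.date:
        return self.entries[(city, year)][1]

    def pre_window(self, city: str, year: int) -> tuple[_dt.date, _dt.date]:
        """Nonheating window [1 May, heating start) of the labelled year."""
        return _dt.date(year, 5, 1), self.start(city, year)

    def post_window(self, city: str, year: int) -> tuple[_dt.date, _dt.date]:
        """Heating window [start, end + 1 day) — half-open, end day included."""
        start, end = self.entries[(city, year)]
        return start, end + _dt.timedelta(days=1)

    def group_start(self, cities: list[str], year: int) -> _dt.date:
        """Anchor date for a treated group: earliest member start."""
        return min(self.start(c, year) for c in cities if (c, year) in self.entries)

    def is_heating(self, city: str, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Boolean mask of hours falling inside any heating season of city."""
        mask = np.zeros(len(timestamps), dtype=bool)
        ts = timestamps.to_numpy()
        for (c, _), (start, end) in self.entries.items():
            if c != city:
                continue
            lo = np.datetime64(pd.Timestamp(start))
            hi = np.datetime64(pd.Timestamp(end) + pd.Timedelta(days=1))
            mask |= (ts >= lo) & (ts < hi)
        return mask

    def to_json(self, path) -> None:
        payload = {
            f"{c}|{y}": [s.isoformat(), e.isoformat()]
            for (c, y), (s, e) in self.entries.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "HeatingCalendar":
        with open(path) as fh:
            payload = json.load(fh)
        entries = {}
        for key, (s, e) in payload.items():
            city, year = key.rsplit("|", 1)
            entries[(city, int(year))] = (
                _dt.date.fromisoformat(s),
                _dt.date.fromisoformat(e),
            )
        return cls(entries)


@dataclass(frozen=True)
class GroupSpec:
    """City group memberships and populations.

    ``groups`` maps a group name (e.g. ``two_plus_26``, ``nonheating``,
    ``alternative``) to its member city ids; ``populations`` maps city id to
    persons. The ``nonheating`` group supplies the synthetic-control donors
    and must have at least two members.
    """

    groups: dict[str, list[str]]
    populations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "nonheating" in self.groups and len(self.groups["nonheating"]) < 2:
            raise ValueError("nonheating (control) group needs >= 2 cities")
        for city, pop in self.populations.items():
            if not pop > 0:
                raise ValueError(f"population of {city} must be positive")

    def members(self, name: str) -> list[str]:
        return list(self.groups[name])

    def population(self, city: str) -> float:
        return self.populations[city]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"groups": self.groups, "populations": self.populations},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroupSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["groups"], payload["populations"])


def _as_hourly(series: pd.Series) -> pd.Series:
    """Reindex to a complete hourly grid (missing hours become NaN)."""
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by timestamps")
    idx = series.index.sort_values()
    full = pd.date_range(idx[0], idx[-1], freq="h")
    return series.reindex(full)


def compute_mda8(hourly_o3: pd.Series) -> pd.Series:
    """Daily maximum 8-hour average ozone (MDA8).

    For every window start hour of a day the forward 8-hour mean is taken
    (valid with >= 6 of 8 hours present); the daily value is the maximum
    over the day's 24 window starts, valid with >= 18 valid windows,
    otherwise NaN. Windows may reach into the first 7 hours of the next day.

    Parameters
    ----------
    hourly_o3 : pd.Series
        Hourly ozone (μg m⁻³) indexed by timestamp; gaps allowed.

    Returns
    -------
    pd.Series indexed by date (normalized timestamps).
    """
    s = _as_hourly(hourly_o3.astype(float))
    # forward-looking 8 h mean: reverse, trailing-roll, reverse back
    rev = s[::-1]
    fwd_mean = rev.rolling(8, min_periods=MIN_HOURS_PER_MDA8_WINDOW).mean()[::-1]
    # trailing windows at the series tail see < 8 hours of data; they stay
    # valid under the >=6/8 rule only if enough hours genuinely exist
    frame = pd.DataFrame({"win": fwd_mean})
    frame["day"] = frame.index.normalize()
    grouped = frame.groupby("day")["win"]
    out = grouped.max()
    out[grouped.count() < MIN_WINDOWS_PER_MDA8_DAY] = np.nan
    out.index.name = "date"
    return out


def compute_ox(no2, o3):
    """Total oxidant Ox (ppbv) from NO2 and O3 mass concentrations.

    Converts each gas from μg m⁻³ to ppbv at 25 °C / 1013 hPa
    (NO2: ÷1.88, O3: ÷1.96) and sums the mixing ratios.
    """
    no2 = np.asarray(no2, dtype=float)
    o3 = np.asarray(o3, dtype=float)
    if np.any(no2[~np.isnan(no2)] < 0) or np.any(o3[~np.isnan(o3)] < 0):
        raise ValueError("negative concentrations are not physical")
    return no2 / _NO2_UG_PER_PPB + o3 / _O3_UG_PER_PPB


def aggregate_daily(hourly: pd.Series, min_hours: int = MIN_HOURS_PER_DAY) -> pd.Series:
    """Daily means of an hourly series; a day needs >= min_hours valid hours."""
    s = _as_hourly(hourly.astype(float))
    day = s.index.normalize()
    grouped = s.groupby(day)
    out = grouped.mean()
    out[grouped.count() < min_hours] = np.nan
    out.index.name = "date"
    return out


def aggregate_weekly(
    daily: pd.Series,
    anchor: _dt.date,
    min_days: int = MIN_DAYS_PER_WEEK,
) -> pd.Series:
    """Weekly means over consecutive 7-day blocks aligned to ``anchor``.

    Block ``k`` covers ``[anchor + 7k, anchor + 7(k+1))`` days for integer
    (possibly negative) ``k``, so the anchor always begins a week. Blocks not
    fully contained in the series' date span are dropped; a retained block
    needs >= min_days valid days. The result is indexed by week start date.
    """
    if daily.empty:
        return pd.Series(dtype=float)
    d = daily.sort_index().astype(float)
    dates = pd.DatetimeIndex(d.index).normalize()
    anchor_ts = pd.Timestamp(anchor)
    offset_days = (dates - anchor_ts).days
    block = np.floor_divide(offset_days, 7)
    week_start = anchor_ts + pd.to_timedelta(block * 7, unit="D")
    grouped = d.groupby(week_start)
    counts = d.groupby(week_start).size()
    out = grouped.mean()
    out[grouped.count() < min_days] = np.nan
    # drop partial terminal blocks: all 7 calendar days must lie in the span
    span_lo, span_hi = dates.min(), dates.max()
    keep = (out.index >= span_lo) & (out.index + pd.Timedelta(days=6) <= span_hi)
    out = out[keep & (counts[out.index] > 0)]
    out.index.name = "week_start"
    return out


def population_weighted(
    city_values: pd.DataFrame, populations: dict[str, float]
) -> pd.Series:
    """Population-weighted mean across cities at each timestamp.

    ``city_values`` has one column per city; weights renormalize over the
    cities with data at each timestamp. All-missing timestamps stay NaN.
    """
    missing = [c for c in city_values.columns if c not in populations]
    if missing:
        raise KeyError(f"no population for cities {missing}")
    w = np.array([populations[c] for c in city_values.columns], dtype=float)
    vals = city_values.to_numpy(dtype=float)
    mask = ~np.isnan(vals)
    wsum = (mask * w).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(
            wsum > 0, np.nansum(vals * w, axis=1) / np.where(wsum > 0, wsum, 1), np.nan
        )
    return pd.Series(out, index=city_values.index)


def split_periods(
    weekly: pd.Series,
    calendar: HeatingCalendar,
    city: str,
    heating_year: int,
    min_weeks: int = 8,
) -> tuple[pd.Series, pd.Series]:
    """Split a weekly series into the pre and post blocks of one heating year.

    Pre: week starts in ``[1 May, heating start)``; post: week starts in
    ``[start, 30 April next year]``. A week belongs to the post block as soon
    as it contains the start date (weeks are anchored to the start date, so
    the boundary is also a week boundary).
    """
    start = pd.Timestamp(calendar.start(city, heating_year))
    pre_lo = pd.Timestamp(_dt.date(heating_year, 5, 1))
    post_hi = pd.Timestamp(_dt.date(heating_year + 1, 4, 30))
    idx = pd.DatetimeIndex(weekly.index)
    pre = weekly[(idx >= pre_lo) & (idx < start)]
    post = weekly[(idx >= start) & (idx <= post_hi)]
    if len(pre) < min_weeks or len(post) < min_weeks:
        raise ValueError(
            f"heating year {heating_year}: {len(pre)} pre / {len(post)} post "
            f"weeks, need >= {min_weeks} of each"
        )
    return pre, post
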