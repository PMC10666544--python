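"""Lunar (Chinese) calendar support for time features.

Emission activity in Chinese cities tracks the lunar calendar around the
Spring Festival (fireworks, travel, industrial shutdowns), so the day of
the lunar year is a useful predictor alongside the Gregorian day of year.
Rather than computing astronomical new moons, we anchor each lunar year at
its (tabulated) Lunar New Year date; the lunar day of year is the number of
days elapsed since the most recent Lunar New Year, starting at 1.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

#: Gregorian date of Lunar New Year (first day of the lunar year), 1990-2030.
LUNAR_NEW_YEAR: dict[int, _dt.date] = {
    1990: _dt.date(1990, 1, 27),
    1991: _dt.date(1991, 2, 15),
    1992: _dt.date(1992, 2, 4),
    1993: _dt.date(1993, 1, 23),
    1994: _dt.date(1994, 2, 10),
    1995: _dt.date(1995, 1, 31),
    1996: _dt.date(1996, 2, 19),
    1997: _dt.date(1997, 2, 7),
    1998: _dt.date(1998, 1, 28),
    1999: _dt.date(1999, 2, 16),
    2000: _dt.date(2000, 2, 5),
    2001: _dt.date(2001, 1, 24),
    2002: _dt.date(2002, 2, 12),
    2003: _dt.date(2003, 2, 1),
    2004: _dt.date(2004, 1, 22),
    2005: _dt.date(2005, 2, 9),
    2006: _dt.date(2006, 1, 29),
    2007: _dt.date(2007, 2, 18),
    2008: _dt.date(2008, 2, 7),
    2009: _dt.date(2009, 1, 26),
    2010: _dt.date(2010, 2, 14),
    2011: _dt.date(2011, 2, 3),
    2012: _dt.date(2012, 1, 23),
    2013: _dt.date(2013, 2, 10),
    2014: _dt.date(2014, 1, 31),
    2015: _dt.date(2015, 2, 19),
    2016: _dt.date(2016, 2, 8),
    2017: _dt.date(2017, 1, 28),
    2018: _dt.date(2018, 2, 16),
    2019: _dt.date(2019, 2, 5),
    2020: _dt.date(2020, 1, 25),
    2021: _dt.date(2021, 2, 12),
    2022: _dt.date(2022, 2, 1),
    2023: _dt.date(2023, 1, 22),
    2024: _dt.date(2024, 2, 10),
    2025: _dt.date(2025, 1, 29),
    2026: _dt.date(2026, 2, 17),
    2027: _dt.date(2027, 2, 6),
    2028: _dt.date(2028, 1, 26),
    2029: _dt.date(2029, 2, 13),
    2030: _dt.date(2030, 2, 3),
}


def lunar_day_of_year(
    dates, lunar_table: dict[int, _dt.date] | None = None
) -> np.ndarray:
    """Day of the lunar year (1-based) for each date.

    The anchor is the most recent Lunar New Year on or before the date, so a
    date equal to a tabulated New Year maps to 1. Values range 1-385 (a lunar
    leap year has 13 months).

    Parameters
    ----------
    dates : array-like of datetime-like
        Dates or timestamps to convert.
    lunar_table : dict, optional
        ``year -> Lunar New Year date``; defaults to the bundled 1990-2030
        table.

    Raises
    ------
    ValueError
        If a date requires an anchor year absent from the table.
    """
    table = LUNAR_NEW_YEAR if lunar_table is None else lunar_table
    idx = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    years = idx.year.to_numpy()
    uniq = {int(y) for y in np.unique(years)}
    needed = uniq | {y - 1 for y in uniq}
    missing = sorted(y for y in needed if y not in table)
    if missing:
        raise ValueError(f"years {missing} missing from Lunar New Year table")
    lny = pd.Series({y: pd.Timestamp(table[y]) for y in needed})
    same_year = lny.loc[years].to_numpy()
    prev_year = lny.loc[years - 1].to_numpy()
    anchor = np.where(idx.to_numpy() < same_year, prev_year, same_year)
    return ((idx.to_numpy() - anchor) / np.timedelta64(1, "D")).astype(np.int64) + 1
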