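"""Pollen-season delineation by cumulative percentage of the annual index.

The annual pollen index of a site/taxon is the sum of its daily mean
concentrations over one calendar year.  The season is delineated by the
cumulative-percentage convention common in aerobiology: it starts on the
first day the running cumulative sum reaches ``start_pct`` percent of the
annual index (default 1%) and ends on the first day it reaches ``end_pct``
percent (default 95%), both days inclusive.

Missing calendar days contribute nothing to the cumulative sum (they are
treated as zero); :attr:`DailySeries.has_gaps` flags their presence so a
data-completeness report can surface them.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSeasonError, InputError

__all__ = [
    "DailySeries",
    "SeasonWindow",
    "annual_pollen_index",
    "season_window",
    "season_windows",
]


@dataclass
class DailySeries:
    """Daily pollen concentrations (pollen/m3) for one taxon at one site.

    ``data`` is a float Series indexed by normalised ``DatetimeIndex``;
    dates must be strictly increasing (no duplicates) and all values finite
    and non-negative.  Calendar gaps are allowed but flagged.
    """

    data: pd.Series
    site: str = ""
    taxon: str = "grass"

    def __post_init__(self):
        s = pd.Series(self.data, dtype=float)
        if not isinstance(s.index, pd.DatetimeIndex):
            s.index = pd.DatetimeIndex(s.index)
        s.index = s.index.normalize()
        if len(s) == 0:
            raise InputError("daily series must not be empty")
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise InputError("dates must be strictly increasing, no duplicates")
        vals = s.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InputError("concentrations must be finite and >= 0")
        self.data = s

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> np.ndarray:
        """Dates as ``datetime.date`` objects."""
        return np.array([ts.date() for ts in self.data.index])

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.data.index.year)))

    @property
    def has_gaps(self) -> bool:
        """True when calendar days are missing between first and last date."""
        span = (self.data.index[-1] - self.data.index[0]).days + 1
        return len(self.data) < span

    def value_on(self, date: dt.date) -> float:
        """Concentration on one date; KeyError when the date is absent."""
        return float(self.data.loc[pd.Timestamp(date)])

    def restrict_to_year(self, year: int) -> "DailySeries":
        sub = self.data[self.data.index.year == year]
        if sub.empty:
            raise InputError(f"series has no data in year {year}")
        return DailySeries(sub, site=self.site, taxon=self.taxon)


@dataclass(frozen=True)
class SeasonWindow:
    """An inclusive [start, end] date window with its delineation metadata."""

    start: dt.date
    end: dt.date
    start_pct: float = 1.0
    end_pct: float = 95.0
    annual_index: float = float("nan")

    def __post_init__(self):
        if self.start > self.end:
            raise InputError("season start must not be after its end")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def days(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]

    def __contains__(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


def annual_pollen_index(series: DailySeries, year: int | None = None) -> float:
    """Sum of daily concentrations over one calendar year (pollen/m3 * days).

    ``year`` may be omitted when the series covers a single calendar year.
    """
    if len(series) == 0:
        raise InputError("empty series has no annual index")
    if year is None:
        years = series.years
        if len(years) > 1:
            raise InputError(
                f"series spans years {years}; pass year= to select one")
        year = years[0]
    sub = series.data[series.data.index.year == year]
    if sub.empty:
        raise InputError(f"series has no data in year {year}")
    return float(sub.sum())


def season_window(series: DailySeries, start_pct: float = 1.0,
                  end_pct: float = 95.0, year: int | None = None
                  ) -> SeasonWindow:
    """Delineate the pollen season of one calendar year.

    The start is the first date whose running cumulative sum reaches
    ``start_pct`` percent of the annual index, the end the first date
    reaching ``end_pct`` percent; both are part of the season.

    Raises
    ------
    DegenerateSeasonError
        When the annual index is zero (all-zero year).
    """
    if not (0 < start_pct < end_pct <= 100):
        raise InputError(
            f"need 0 < start_pct < end_pct <= 100, got {start_pct}, {end_pct}")
    if year is None:
        years = series.years
        if len(years) > 1:
            raise InputError(
                f"series spans years {years}; pass year= to select one")
        year = years[0]
    sub = series.data[series.data.index.year == year]
    if sub.empty:
        raise InputError(f"series has no data in year {year}")
    index_total = float(sub.sum())
    if index_total <= 0:
        raise DegenerateSeasonError(
            f"annual pollen index is 0 in {year}; no season exists")
    csum = sub.cumsum().to_numpy()
    # first index reaching each threshold; >= comparison, thresholds as
    # exact fractions of the realised total
    start_i = int(np.argmax(csum >= start_pct / 100.0 * index_total))
    end_i = int(np.argmax(csum >= end_pct / 100.0 * index_total))
    return SeasonWindow(start=sub.index[start_i].date(),
                        end=sub.index[end_i].date(),
                        start_pct=start_pct, end_pct=end_pct,
                        annual_index=index_total)


def season_windows(series: DailySeries, start_pct: float = 1.0,
                   end_pct: float = 95.0) -> dict[int, SeasonWindow]:
    """Season window per calendar year of a (possibly multi-year) series.

    Years whose annual index is zero are skipped.
    """
    out: dict[int, SeasonWindow] = {}
    for year in series.years:
        try:
            out[year] = season_window(series, start_pct, end_pct, year=year)
        except DegenerateSeasonError:
            continue
    return out
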