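"""Hit rates, availability, and forecast-distribution summaries.

The central score is the *hit rate*: the percentage of days in an
evaluation window on which the forecast category's concentration band —
optionally widened by a symmetric tolerance of ``t`` pollen/m3 — contains
the measured concentration.  Hit rates are computed for a list of
tolerances (default exact, +/-2, +/-4) and are non-decreasing in the
tolerance by construction.

Missing forecasts never count as correct; whether they count in the
denominator is controlled by ``denominator_mode``:

``all_days``
    denominator = every day of the window; a missing forecast is a miss.
``available``
    denominator = days with a non-missing forecast.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import ClassificationScheme, is_hit
from .errors import InputError
from .season import DailySeries, SeasonWindow

__all__ = [
    "MISSING",
    "ForecastSeries",
    "ToleranceResult",
    "HitRateReport",
    "ForecastProfile",
    "evaluate",
    "availability",
    "forecast_profile",
]

#: Sentinel for a day without a forecast.
MISSING = None

DENOMINATOR_MODES = ("available", "all_days")


@dataclass
class ForecastSeries:
    """Dated categorical forecasts for one provider ("app").

    ``data`` is an object Series indexed by normalised ``DatetimeIndex``
    whose values are label strings or ``None`` (missing).  Dates must be
    strictly increasing.  Labels are validated against a scheme at parse
    time (:func:`pollenverify.io.read_forecast_series`) or via
    :meth:`validate_labels`.
    """

    data: pd.Series
    app_name: str = ""
    scheme_name: str = ""

    def __post_init__(self):
        s = pd.Series(self.data, dtype=object)
        if not isinstance(s.index, pd.DatetimeIndex):
            s.index = pd.DatetimeIndex(s.index)
        s.index = s.index.normalize()
        if len(s) == 0:
            raise InputError("forecast series must not be empty")
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise InputError("dates must be strictly increasing, no duplicates")
        # normalise NaN-ish values to the MISSING sentinel
        vals = np.array([MISSING if pd.isna(v) else v for v in s.to_numpy()],
                        dtype=object)
        self.data = pd.Series(vals, index=s.index, dtype=object)

    def __len__(self) -> int:
        return len(self.data)

    def label_on(self, date: dt.date):
        """Label for one date; absent dates count as MISSING."""
        try:
            v = self.data.loc[pd.Timestamp(date)]
        except KeyError:
            return MISSING
        return v

    def validate_labels(self, scheme: ClassificationScheme) -> None:
        known = set(scheme.labels)
        bad = {v for v in self.data if v is not MISSING and v not in known}
        if bad:
            raise InputError(
                f"labels {sorted(bad)} not in scheme {scheme.name!r}")


@dataclass(frozen=True)
class ToleranceResult:
    tolerance: float
    n_correct: int
    hit_rate: float  # percent, rounded to one decimal


@dataclass(frozen=True)
class HitRateReport:
    """Per-tolerance verification scores for one app over one window."""

    app_name: str
    window: SeasonWindow
    n_days: int
    n_available: int
    per_tolerance: tuple[ToleranceResult, ...]
    denominator_mode: str
    overlap_rule: bool

    @property
    def availability_fraction(self) -> float:
        return self.n_available / self.n_days if self.n_days else 0.0

    def hit_rate(self, tolerance: float) -> float:
        for r in self.per_tolerance:
            if r.tolerance == tolerance:
                return r.hit_rate
        raise KeyError(tolerance)


@dataclass(frozen=True)
class ForecastProfile:
    """Distribution of one app's forecast labels inside a window.

    ``counts`` includes every scheme label plus the key ``"NA"`` for missing
    days and sums to the window length.  The quartiles and mean are on the
    ordinal coding of the scheme (plain classes 0..k-1, intermediates at
    pair midpoints), computed over non-missing days; they are ``nan`` when
    every day is missing.
    """

    app_name: str
    counts: dict[str, int]
    q25: float
    q50: float
    q75: float
    mean: float


def _window_days(window: SeasonWindow) -> list[dt.date]:
    return window.days()


def evaluate(forecasts: ForecastSeries, observations: DailySeries,
             window: SeasonWindow, scheme: ClassificationScheme,
             tolerances=(0.0, 2.0, 4.0), denominator_mode: str = "all_days",
             overlap_rule: bool = True) -> HitRateReport:
    """Score a forecast series against observations inside a window.

    For each tolerance, ``n_correct`` counts the window days on which
    :func:`pollenverify.classification.is_hit` holds for the day's forecast
    and observation.  An observation must exist for every window day.

    Raises
    ------
    InputError
        When tolerances are negative or unsorted, an observation is missing
        on a window day (the error names the date), or no forecast date
        falls inside the window at all.
    """
    tolerances = tuple(float(t) for t in tolerances)
    if any(t < 0 for t in tolerances) or list(tolerances) != sorted(tolerances):
        raise InputError(f"tolerances must be >= 0 and sorted: {tolerances}")
    if denominator_mode not in DENOMINATOR_MODES:
        raise InputError(
            f"denominator_mode must be one of {DENOMINATOR_MODES}")
    days = _window_days(window)
    fc_dates = {ts.date() for ts in forecasts.data.index}
    if not fc_dates.intersection(days):
        raise InputError(
            f"forecast series {forecasts.app_name!r} has no dates inside "
            f"the window {window.start}..{window.end}")
    obs: list[float] = []
    labels: list = []
    for day in days:
        try:
            obs.append(observations.value_on(day))
        except KeyError:
            raise InputError(
                f"no observation on window day {day.isoformat()}") from None
        labels.append(forecasts.label_on(day))
    n_days = len(days)
    n_available = sum(lbl is not MISSING for lbl in labels)
    denom = n_days if denominator_mode == "all_days" else n_available
    if denom == 0:
        raise InputError(
            "no available forecasts in window under 'available' mode")
    results = []
    for t in tolerances:
        n_correct = sum(
            1 for lbl, x in zip(labels, obs)
            if lbl is not MISSING and is_hit(lbl, x, t, scheme, overlap_rule))
        results.append(ToleranceResult(
            tolerance=t, n_correct=n_correct,
            hit_rate=round(100.0 * n_correct / denom, 1)))
    return HitRateReport(
        app_name=forecasts.app_name, window=window, n_days=n_days,
        n_available=n_available, per_tolerance=tuple(results),
        denominator_mode=denominator_mode, overlap_rule=overlap_rule)


def availability(forecasts: ForecastSeries, window: SeasonWindow
                 ) -> tuple[int, int, float]:
    """Forecast availability inside a window.

    Returns ``(n_days, n_available, fraction)`` where ``n_available``
    counts window days with a non-missing forecast.
    """
    days = _window_days(window)
    n_available = sum(forecasts.label_on(d) is not MISSING for d in days)
    n_days = len(days)
    return n_days, n_available, (n_available / n_days if n_days else 0.0)


def forecast_profile(forecasts: ForecastSeries, window: SeasonWindow,
                     scheme: ClassificationScheme) -> ForecastProfile:
    """Label counts and ordinal summary of the forecasts inside a window."""
    days = _window_days(window)
    counts = {label: 0 for label in scheme.labels}
    counts["NA"] = 0
    codes: list[float] = []
    for d in days:
        lbl = forecasts.label_on(d)
        if lbl is MISSING:
            counts["NA"] += 1
        else:
            counts[lbl] = counts.get(lbl, 0) + 1
            codes.append(scheme.ordinal_code(lbl))
    if codes:
        q25, q50, q75 = np.percentile(codes, [25, 50, 75], method="midpoint")
        mean = float(np.mean(codes))
    else:
        q25 = q50 = q75 = mean = float("nan")
    return ForecastProfile(app_name=forecasts.app_name, counts=counts,
                           q25=float(q25), q50=float(q50), q75=float(q75),
                           mean=mean)
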