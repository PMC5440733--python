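"""Verification of flowering-onset ("readiness to flower") forecasts.

Some pollen services forecast the date on which grasses start flowering.
That date is verified against the first day the observed concentration
reaches a threshold load class — by default the first *moderate-or-higher*
day, since scattered low loads can precede the season proper, and a day
that jumps straight to a high load still marks onset.

The reported offset is signed: ``forecast_date - event_date`` in calendar
days, so a positive offset means the forecast came after the event.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .classification import ClassificationScheme, PLAIN
from .errors import InputError, NoEventError
from .season import DailySeries, SeasonWindow

__all__ = ["OnsetVerification", "first_threshold_day", "onset_offset"]


@dataclass(frozen=True)
class OnsetVerification:
    forecast_date: dt.date
    event_date: dt.date
    offset_days: int  # forecast - event, sign preserved
    event_threshold_label: str = "moderate"


def first_threshold_day(series: DailySeries, scheme: ClassificationScheme,
                        label: str = "moderate",
                        window: SeasonWindow | None = None) -> dt.date:
    """Earliest date whose concentration reaches ``label``'s band or higher.

    The search covers the full series by default; pass ``window`` to
    restrict it to a delineated season.

    Raises
    ------
    NoEventError
        When the threshold is never reached.
    """
    cls = scheme.class_for(label)
    if cls.kind != PLAIN:
        raise InputError(f"threshold label must be a plain class, got {label!r}")
    threshold = cls.lower
    for ts, value in series.data.items():
        day = ts.date()
        if window is not None and day not in window:
            continue
        if value >= threshold:
            return day
    raise NoEventError(
        f"load {label!r} (>= {threshold} pollen/m3) never reached"
        + ("" if window is None else f" inside {window.start}..{window.end}"))


def onset_offset(forecast_date: dt.date, series: DailySeries,
                 scheme: ClassificationScheme, label: str = "moderate",
                 window: SeasonWindow | None = None) -> OnsetVerification:
    """Signed day offset of an onset forecast from the first threshold day.

    ``offset_days = forecast_date - event_date``; 0 means same-day, a
    negative value a forecast that preceded the event.
    """
    event = first_threshold_day(series, scheme, label=label, window=window)
    offset = (forecast_date - event).days
    return OnsetVerification(forecast_date=forecast_date, event_date=event,
                             offset_days=offset, event_threshold_label=label)
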