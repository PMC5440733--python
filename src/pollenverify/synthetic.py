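"""Synthetic pollen seasons and forecasters of controlled skill.

Nothing in the verification pipeline depends on real monitoring data; this
module generates observation series with the seasonal structure the
analysis assumes, and forecast series from forecasters whose error process
is known, so every stage can be exercised end to end.

The observation model is a unimodal season: a triangular weight curve over
``[season_start_doy, season_end_doy]`` peaking at ``season_peak_doy``,
scaled to a target annual pollen index, with multiplicative lognormal
day-to-day noise of median 1.  Lognormal noise keeps concentrations
positive and right-skewed, as daily pollen counts are.  Defaults emulate a
central-European grass season: roughly May to mid-August, peaking in early
June, with an annual index of a few thousand pollen/m3*days.

Forecasters:

``oracle``
    Relabels the true observation — a perfect categorical forecast.
``additive_noise``
    Estimates the concentration with additive Gaussian error of standard
    deviation ``noise_sd`` (floored at 0), then bins it.  Noise acts in
    concentration space before classification, mimicking a forecaster that
    estimates a level and then bins it; this is what makes boundary
    tolerances meaningful.
``class_bias``
    The oracle label shifted by a fixed number of classes, clamped to the
    scale — a systematically over- or under-warning provider.
``climatology``
    The same fixed label every day.

Independently of the kind, each day's forecast is replaced by MISSING with
probability ``missing_prob``.  All randomness flows from explicit integer
seeds; no global random state is touched.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import ClassificationScheme, classify_many
from .errors import InputError
from .season import DailySeries
from .verification import MISSING, ForecastSeries

__all__ = [
    "SeasonSimConfig",
    "ForecasterSpec",
    "simulate_season",
    "simulate_forecaster",
]

FORECASTER_KINDS = ("oracle", "additive_noise", "class_bias", "climatology")


@dataclass(frozen=True)
class SeasonSimConfig:
    """Parameters of one simulated pollen year.

    Day-of-year defaults place the season from May 1 (doy 121) through
    mid-August (doy 230) with an early-June peak (doy 160), the shape of a
    long, comparatively smooth central-European grass pollen season.
    """

    year: int = 2016
    season_start_doy: int = 121
    season_peak_doy: int = 160
    season_end_doy: int = 230
    annual_index_target: float = 3000.0
    noise_sd_log: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.season_start_doy < self.season_peak_doy
                < self.season_end_doy <= 366):
            raise InputError(
                "need 1 <= start < peak < end <= 366 day-of-year, got "
                f"{self.season_start_doy}, {self.season_peak_doy}, "
                f"{self.season_end_doy}")
        if self.annual_index_target <= 0:
            raise InputError("annual_index_target must be > 0")
        if self.noise_sd_log < 0:
            raise InputError("noise_sd_log must be >= 0")


@dataclass(frozen=True)
class ForecasterSpec:
    """Error process of one simulated forecast provider."""

    kind: str = "oracle"
    noise_sd: float = 0.0      # pollen/m3, additive_noise only
    bias_classes: int = 0      # class_bias only, signed
    fixed_label: str | None = None  # climatology only
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FORECASTER_KINDS:
            raise InputError(
                f"unknown forecaster kind {self.kind!r}; "
                f"known: {', '.join(FORECASTER_KINDS)}")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if not 0 <= self.missing_prob <= 1:
            raise InputError("missing_prob must lie in [0, 1]")
        if self.kind == "climatology" and self.fixed_label is None:
            raise InputError("climatology forecaster needs fixed_label")

    @property
    def name(self) -> str:
        """Human-readable provider name for reports."""
        if self.kind == "additive_noise":
            core = f"additive_noise(sd={self.noise_sd:g})"
        elif self.kind == "class_bias":
            core = f"class_bias({self.bias_classes:+d})"
        elif self.kind == "climatology":
            core = f"climatology({self.fixed_label})"
        else:
            core = "oracle"
        if self.missing_prob > 0:
            core += f"+miss({self.missing_prob:g})"
        return core


def simulate_season(config: SeasonSimConfig) -> DailySeries:
    """Simulate one full calendar year of daily concentrations.

    Daily values are ``annual_index_target * w_d * eps_d`` with ``w_d`` a
    triangular weight curve over the season (zero outside it, summing to 1)
    and ``eps_d`` lognormal with median 1 and log-sd ``noise_sd_log``; the
    result is rescaled so the realised annual index equals the target
    exactly.  The same seed always yields the same series.
    """
    ndays = 366 if calendar.isleap(config.year) else 365
    doy = np.arange(1, ndays + 1, dtype=float)
    start, peak, end = (float(config.season_start_doy),
                        float(config.season_peak_doy),
                        float(config.season_end_doy))
    w = np.zeros(ndays)
    rising = (doy >= start) & (doy <= peak)
    falling = (doy > peak) & (doy <= end)
    # ramp strictly positive at the season start, zero at the season end
    w[rising] = (doy[rising] - start + 1.0) / (peak - start + 1.0)
    w[falling] = (end - doy[falling]) / (end - peak)
    w /= w.sum()
    rng = np.random.default_rng(config.seed)
    eps = rng.lognormal(mean=0.0, sigma=config.noise_sd_log, size=ndays)
    conc = config.annual_index_target * w * eps
    conc *= config.annual_index_target / conc.sum()
    dates = pd.date_range(dt.date(config.year, 1, 1), periods=ndays, freq="D")
    series = pd.Series(conc, index=dates)
    site = f"sim-{config.year}-seed{config.seed}"
    return DailySeries(series, site=site, taxon="grass")


def simulate_forecaster(observations: DailySeries, spec: ForecasterSpec,
                        scheme: ClassificationScheme) -> ForecastSeries:
    """Generate a categorical forecast series for given observations.

    The label process depends on ``spec.kind`` (see the module docstring);
    afterwards each day is independently replaced by MISSING with
    probability ``spec.missing_prob``.  Reproducible under ``spec.seed``:
    the label noise is drawn first for all days, then the missingness mask.
    """
    rng = np.random.default_rng(spec.seed)
    x = observations.values
    n = len(x)
    if spec.kind == "oracle":
        labels = classify_many(x, scheme)
    elif spec.kind == "additive_noise":
        noisy = np.maximum(0.0, x + rng.normal(0.0, spec.noise_sd, size=n))
        labels = classify_many(noisy, scheme)
    elif spec.kind == "class_bias":
        plain = scheme.plain_labels
        lowers = np.array([scheme.class_for(p).lower for p in plain])
        idx = np.searchsorted(lowers, x, side="right") - 1
        idx = np.clip(idx + spec.bias_classes, 0, len(plain) - 1)
        labels = np.asarray(plain, dtype=object)[idx]
    else:  # climatology
        scheme.class_for(spec.fixed_label)  # validates the label
        labels = np.full(n, spec.fixed_label, dtype=object)
    labels = labels.astype(object)
    if spec.missing_prob > 0:
        missing = rng.random(n) < spec.missing_prob
        labels[missing] = MISSING
    data = pd.Series(labels, index=observations.data.index, dtype=object)
    return ForecastSeries(data, app_name=spec.name, scheme_name=scheme.name)
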