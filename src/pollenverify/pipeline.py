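"""End-to-end run configuration and orchestration.

:func:`run_pipeline` ties the modules together the way the evaluation
procedure prescribes: delineate the pollen season from the observations,
score every forecast file inside that window, summarise each provider's
forecast distribution and availability, optionally verify a
readiness-to-flower date, and write all reports.  Everything is computed
before anything is written, and each report is written atomically, so a
failing run never leaves partial output.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .errors import InputError
from .onset import OnsetVerification, onset_offset
from .season import DailySeries, SeasonWindow, season_window
from .verification import (ForecastProfile, ForecastSeries, HitRateReport,
                           availability, evaluate, forecast_profile)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("pollenverify")


@dataclass
class RunConfig:
    """Everything one evaluation run needs, reproducibly."""

    observations: str
    forecasts: list[str] = field(default_factory=list)
    scheme: str = "default"
    tolerances: tuple[float, ...] = (0.0, 2.0, 4.0)
    denominator_mode: str = "all_days"
    overlap_rule: bool = True
    start_pct: float = 1.0
    end_pct: float = 95.0
    year: int | None = None
    onset_forecast_date: dt.date | None = None
    onset_label: str = "moderate"
    out_dir: str = "."
    seed: int | None = None

    def __post_init__(self):
        tols = tuple(float(t) for t in self.tolerances)
        if any(t < 0 for t in tols) or list(tols) != sorted(tols):
            raise InputError(f"tolerances must be >= 0 and sorted: {tols}")
        self.tolerances = tols
        if not self.forecasts:
            raise InputError("at least one forecast file is required")


@dataclass
class PipelineResult:
    window: SeasonWindow
    observations: DailySeries
    reports: list[HitRateReport]
    profiles: list[ForecastProfile]
    onsets: list[tuple[str, OnsetVerification]]
    paths: dict[str, str]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run season delineation, verification and reporting for one site-year.

    Writes ``hit_rates.tsv``, ``profiles.tsv``, ``season.tsv`` and, when an
    onset forecast date is configured, ``onset.tsv`` into ``out_dir``.  The
    report headers record the scheme hash, tolerances, modes and seed.
    """
    scheme = pio.load_scheme(config.scheme)
    obs = pio.read_daily_series(config.observations)
    window = season_window(obs, config.start_pct, config.end_pct,
                           year=config.year)
    log.info("season window %s..%s (%d days, annual index %.1f)",
             window.start, window.end, window.n_days, window.annual_index)

    forecast_series: list[ForecastSeries] = [
        pio.read_forecast_series(p, scheme) for p in config.forecasts]
    reports, profiles = [], []
    for fc in forecast_series:
        rep = evaluate(fc, obs, window, scheme,
                       tolerances=config.tolerances,
                       denominator_mode=config.denominator_mode,
                       overlap_rule=config.overlap_rule)
        n_days, n_avail, frac = availability(fc, window)
        log.info("%s: available %d/%d (%.1f%%), hit rates %s",
                 fc.app_name, n_avail, n_days, 100 * frac,
                 ", ".join(f"t{r.tolerance:g}={r.hit_rate:.1f}%"
                           for r in rep.per_tolerance))
        reports.append(rep)
        profiles.append(forecast_profile(fc, window, scheme))
    onsets: list[tuple[str, OnsetVerification]] = []
    if config.onset_forecast_date is not None:
        ver = onset_offset(config.onset_forecast_date, obs, scheme,
                           label=config.onset_label)
        log.info("onset: forecast %s vs event %s -> %+d days",
                 ver.forecast_date, ver.event_date, ver.offset_days)
        onsets.append((obs.site or "observations", ver))

    meta = {
        "scheme": scheme.name,
        "scheme_hash": pio.scheme_hash(scheme),
        "denominator_mode": config.denominator_mode,
        "overlap_rule": config.overlap_rule,
        "tolerances": ",".join(f"{t:g}" for t in config.tolerances),
        "start_pct": f"{config.start_pct:g}",
        "end_pct": f"{config.end_pct:g}",
        "window": f"{window.start.isoformat()}..{window.end.isoformat()}",
        "seed": config.seed,
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"hit_rates": str(out / "hit_rates.tsv"),
             "profiles": str(out / "profiles.tsv"),
             "season": str(out / "season.tsv")}
    pio.write_hit_rate_report(paths["hit_rates"], reports, meta)
    pio.write_profile_report(paths["profiles"], profiles, scheme, meta)
    pio.write_season_report(paths["season"], obs,
                            {window.start.year: window}, meta)
    if onsets:
        paths["onset"] = str(out / "onset.tsv")
        pio.write_onset_report(paths["onset"], onsets, meta)
    return PipelineResult(window=window, observations=obs, reports=reports,
                          profiles=profiles, onsets=onsets, paths=paths)
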