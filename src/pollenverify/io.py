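"""Readers and writers for the delimited-text formats of the pipeline.

Observation files carry columns ``date`` (ISO 8601) and ``concentration``
(pollen/m3); forecast files carry ``date`` and ``label``, where the literal
token ``NA`` (case-insensitive) or an empty field marks a missing forecast.
The delimiter is auto-detected between comma and tab; all output is
tab-separated.  Parse errors name the file and 1-based line number.

Report writers prefix their tables with ``#``-comment header lines that
record the exact configuration (scheme hash, tolerances, modes, seed)
needed to reproduce the numbers.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import json
import os
from pathlib import Path

import pandas as pd

from .classification import ClassificationScheme, default_scheme
from .errors import ParseError
from .onset import OnsetVerification
from .season import DailySeries, SeasonWindow
from .verification import (MISSING, ForecastProfile, ForecastSeries,
                           HitRateReport)

__all__ = [
    "read_daily_series",
    "write_daily_series",
    "read_forecast_series",
    "write_forecast_series",
    "load_scheme",
    "scheme_hash",
    "write_season_report",
    "write_hit_rate_report",
    "write_profile_report",
    "write_onset_report",
]


# -- low-level table reading ----------------------------------------------

def _read_table(path, required: tuple[str, str]):
    """Yield (line_number, {col: value}) rows from a comma- or tab-delimited
    file with a header containing the two required columns."""
    path = os.fspath(path)
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(str(exc), path=path) from None
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty file", path=path)
    delimiter = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(lines, delimiter=delimiter))
    header = [h.strip().lower() for h in rows[0]]
    col_idx = {}
    for col in required:
        if col not in header:
            raise ParseError(
                f"missing required column {col!r} (header: {header})",
                path=path, line=1)
        col_idx[col] = header.index(col)
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) < len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(row)}",
                path=path, line=lineno)
        yield lineno, {col: row[i].strip() for col, i in col_idx.items()}


def _parse_date(value: str, path: str, lineno: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        raise ParseError(f"malformed ISO date {value!r}",
                         path=path, line=lineno) from None


# -- daily observation series ---------------------------------------------

def read_daily_series(path, site: str = "", taxon: str = "grass"
                      ) -> DailySeries:
    """Parse a daily concentration file into a date-sorted
    :class:`~pollenverify.season.DailySeries`.

    Rejects malformed dates, negative or non-numeric concentrations and
    duplicate dates, naming the offending line.
    """
    path = os.fspath(path)
    seen: dict[dt.date, int] = {}
    dates: list[dt.date] = []
    values: list[float] = []
    for lineno, row in _read_table(path, ("date", "concentration")):
        day = _parse_date(row["date"], path, lineno)
        if day in seen:
            raise ParseError(
                f"duplicate date {day.isoformat()} (first seen on line "
                f"{seen[day]})", path=path, line=lineno)
        seen[day] = lineno
        try:
            conc = float(row["concentration"])
        except ValueError:
            raise ParseError(
                f"non-numeric concentration {row['concentration']!r}",
                path=path, line=lineno) from None
        if not conc >= 0:
            raise ParseError(
                f"negative concentration {conc}", path=path, line=lineno)
        dates.append(day)
        values.append(conc)
    if not dates:
        raise ParseError("no data rows", path=path)
    order = sorted(range(len(dates)), key=dates.__getitem__)
    series = pd.Series([values[i] for i in order],
                       index=pd.DatetimeIndex([dates[i] for i in order]))
    return DailySeries(series, site=site, taxon=taxon)


def write_daily_series(path, series: DailySeries) -> None:
    """Write a daily series as tab-separated ``date``/``concentration``.

    Concentrations use shortest-round-trip float formatting, so a
    write-then-read cycle reproduces the series exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("date\tconcentration\n")
        for ts, value in series.data.items():
            fh.write(f"{ts.date().isoformat()}\t{float(value)!r}\n")


# -- categorical forecast series ------------------------------------------

def read_forecast_series(path, scheme: ClassificationScheme,
                         app_name: str | None = None) -> ForecastSeries:
    """Parse a forecast file; labels are validated against ``scheme``.

    ``NA`` (case-insensitive) and empty label fields parse as MISSING.
    The app name defaults to the file's stem.
    """
    path = os.fspath(path)
    known = set(scheme.labels)
    seen: dict[dt.date, int] = {}
    dates: list[dt.date] = []
    labels: list = []
    for lineno, row in _read_table(path, ("date", "label")):
        day = _parse_date(row["date"], path, lineno)
        if day in seen:
            raise ParseError(
                f"duplicate date {day.isoformat()} (first seen on line "
                f"{seen[day]})", path=path, line=lineno)
        seen[day] = lineno
        raw = row["label"]
        if raw == "" or raw.lower() == "na":
            labels.append(MISSING)
        elif raw in known:
            labels.append(raw)
        else:
            raise ParseError(
                f"unknown label {raw!r} for scheme {scheme.name!r} "
                f"(known: {', '.join(scheme.labels)})",
                path=path, line=lineno)
        dates.append(day)
    if not dates:
        raise ParseError("no data rows", path=path)
    order = sorted(range(len(dates)), key=dates.__getitem__)
    data = pd.Series([labels[i] for i in order],
                     index=pd.DatetimeIndex([dates[i] for i in order]),
                     dtype=object)
    if app_name is None:
        app_name = Path(path).stem
    return ForecastSeries(data, app_name=app_name, scheme_name=scheme.name)


def write_forecast_series(path, forecasts: ForecastSeries) -> None:
    """Write a forecast series as tab-separated ``date``/``label``;
    missing days are written as ``NA``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("date\tlabel\n")
        for ts, label in forecasts.data.items():
            token = "NA" if label is MISSING else str(label)
            fh.write(f"{ts.date().isoformat()}\t{token}\n")


# -- classification scheme config -----------------------------------------

def load_scheme(name_or_path: str = "default") -> ClassificationScheme:
    """Load a scheme: ``"default"`` for the packaged one, else a JSON path."""
    if name_or_path == "default":
        return default_scheme()
    path = os.fspath(name_or_path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise ParseError(str(exc), path=path) from None
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", path=path) from None
    try:
        return ClassificationScheme.from_dict(doc)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"invalid scheme config: {exc}", path=path) from None


def scheme_hash(scheme: ClassificationScheme) -> str:
    """Short stable digest of a scheme's full numeric definition."""
    canon = json.dumps(scheme.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]


# -- report writers --------------------------------------------------------

def _write_report(path, meta: dict, header: list[str],
                  rows: list[list]) -> None:
    """Write a tab-separated report with ``# key: value`` comment lines.

    The file is written atomically (temp file + rename) so an error never
    leaves a partial report behind.
    """
    tmp = os.fspath(path) + ".tmp"
    with open(tmp, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    os.replace(tmp, path)


def _fmt(x: float) -> str:
    return "nan" if x != x else f"{x:.6g}"


def write_season_report(path, series: DailySeries,
                        windows: dict[int, SeasonWindow],
                        meta: dict | None = None) -> None:
    rows = [[series.site, series.taxon, year, w.start.isoformat(),
             w.end.isoformat(), w.n_days, _fmt(w.annual_index),
             _fmt(w.start_pct), _fmt(w.end_pct)]
            for year, w in sorted(windows.items())]
    _write_report(path, meta or {},
                  ["site", "taxon", "year", "start", "end", "n_days",
                   "annual_index", "start_pct", "end_pct"], rows)


def write_hit_rate_report(path, reports: list[HitRateReport],
                          meta: dict | None = None) -> None:
    """One row per app, hit-rate columns mirroring the usual exact / +/-2 /
    +/-4 presentation plus availability columns."""
    if not reports:
        raise ValueError("no reports to write")
    tolerances = [r.tolerance for r in reports[0].per_tolerance]
    header = ["app", "window_start", "window_end", "n_days", "n_available",
              "availability_pct"]
    for t in tolerances:
        header += [f"n_correct_t{t:g}", f"hit_rate_t{t:g}"]
    rows = []
    for rep in reports:
        if [r.tolerance for r in rep.per_tolerance] != tolerances:
            raise ValueError("reports have differing tolerance lists")
        row = [rep.app_name, rep.window.start.isoformat(),
               rep.window.end.isoformat(), rep.n_days, rep.n_available,
               f"{100.0 * rep.availability_fraction:.1f}"]
        for r in rep.per_tolerance:
            row += [r.n_correct, f"{r.hit_rate:.1f}"]
        rows.append(row)
    base = {"denominator_mode": reports[0].denominator_mode,
            "overlap_rule": reports[0].overlap_rule,
            "tolerances": ",".join(f"{t:g}" for t in tolerances)}
    _write_report(path, {**base, **(meta or {})}, header, rows)


def write_profile_report(path, profiles: list[ForecastProfile],
                         scheme: ClassificationScheme,
                         meta: dict | None = None) -> None:
    labels = list(scheme.labels) + ["NA"]
    header = (["app"] + [f"n_{lbl}" for lbl in labels]
              + ["q25", "q50", "q75", "mean"])
    rows = [[p.app_name] + [p.counts.get(lbl, 0) for lbl in labels]
            + [_fmt(p.q25), _fmt(p.q50), _fmt(p.q75), _fmt(p.mean)]
            for p in profiles]
    _write_report(path, meta or {}, header, rows)


def write_onset_report(path, verifications: list[tuple[str, OnsetVerification]],
                       meta: dict | None = None) -> None:
    rows = [[app, v.forecast_date.isoformat(), v.event_date.isoformat(),
             v.offset_days, v.event_threshold_label]
            for app, v in verifications]
    _write_report(path, meta or {},
                  ["app", "forecast_date", "event_date", "offset_days",
                   "threshold_label"], rows)
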