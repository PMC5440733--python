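# Methods

## Scope and model

The package verifies *categorical* daily pollen forecasts against measured
daily mean concentrations (pollen grains per cubic meter). The verified
quantity is the agreement of the forecast load class with the class of the
measurement — not a numerical forecast error — because that is what the
services publish and what an allergy sufferer acts on. Three statistics are
produced: tolerance-banded hit rates inside a delineated pollen season,
forecast availability and distribution summaries, and the signed day offset
of a flowering-onset forecast.

## Load classes and the half-open convention

Published class tables print bands at one-decimal resolution ("0–0.99",
"1–19.9", "20–49.9", "50 and above"), which leaves real-valued gaps (e.g.
0.995). Internally plain classes are half-open, `[0,1), [1,20), [20,50),
[50,∞)`: every non-negative concentration maps to exactly one class, and
every printed bound is honoured. The scheme is a JSON config (label, lower,
upper-or-null per class) so national variants can be swapped in; validation
enforces contiguity, a zero origin and an unbounded top class.

## Intermediate overlap intervals

Providers issuing intermediate steps (no-low, low-moderate, moderate-high)
are handled by giving each intermediate class a numeric interval centred
between the pair's boundaries with a ±20% span: with centre
`c = (lower bound of the upper class) − 0.5` and fraction `f` (default
0.2), the interval is `[c(1−f), c(1+f)]`. The −0.5 centring reads the
boundary as the midpoint between the upper class's lower bound and the
lower class's last printed one-decimal value; it reproduces the published
low-moderate (15.6–23.4) and moderate-high (39.6–59.4) intervals exactly.
The published no-low band (0–2) follows no fractional rule and is stored
as a configured literal. Formula results are rounded to 9 decimals so that
binary float noise (19.5·0.8 = 15.600000000000001) cannot shift a
one-decimal band edge. Intermediate intervals are treated as closed; their
printed endpoints belong to the interval.

## Hit rule

A forecast label verifies on a day when the observation lies in the
label's band widened symmetrically by the tolerance `t` at both ends,
floored at zero (an unbounded top stays unbounded). Tolerances are in
pollen/m³ — the same units as the bands — with the conventional ladder
0, ±2, ±4. Under the *overlap rule*, an observation falling in an
intermediate interval credits both neighbouring plain classes (and the
intermediate class itself); the intermediate interval is widened by the
same tolerance. Published procedures of this kind sometimes state the
overlap counting only for the exact match; we apply it at every tolerance,
controlled by a flag
(`overlap_rule=False` restores exact-only-style scoring), because the
rationale — an observation in the declared overlap region is consistent
with either label — does not depend on the tolerance. Hit rates are
reported in percent rounded to one decimal.

## Denominators and missing forecasts

Missing forecasts never count as correct. Two denominator modes exist:
`all_days` (the default; a missing forecast is a miss, so unreliable
services score lower) and `available` (only days with a forecast count).
The mode is recorded in every report, and availability (n available / n
window days) is always reported alongside, so the two modes can be
reconciled.

## Season delineation

The evaluation window is the 1–95% season: the annual pollen index is the
calendar-year sum of daily concentrations; the season starts on the first
day the running cumulative sum reaches 1% of it and ends on the first day
it reaches 95%, both inclusive. "First day reaching" (≥) is used at both
ends — the alternative "last day below" convention differs by at most one
day and is not exposed. Missing calendar days contribute zero to the
cumulative sum; their presence is flagged (`DailySeries.has_gaps`).
Multi-year series are delineated per calendar year.

## Onset verification

The flowering-onset event is the first day the observed load reaches
*moderate or higher* — not exactly moderate — since a day jumping straight
to the high band still marks the season onset, while scattered low loads
can precede it. The reported offset is `forecast_date − event_date` in
calendar days (pure dates, no time zones): positive means the forecast
came after the event. By default the search covers the whole series, since
the first moderate day can precede the 1% season start; a window argument
restricts it.

## Synthetic generator

The simulator emulates one calendar year of a central-European grass
pollen season: a triangular weight curve over day-of-year
[`season_start_doy`, `season_end_doy`] peaking at `season_peak_doy`
(defaults 121 / 160 / 230 — May 1 through mid-August, early-June peak, the
shape of a long and comparatively smooth season), scaled so the annual
index hits `annual_index_target` (default 3000 pollen/m³·days, a typical
order for urban grass stations), with multiplicative lognormal day-to-day
noise of median 1 and log-sd `noise_sd_log` (default 0.5). After noising,
the year is rescaled so the realised index equals the target exactly.

Forecasters: `oracle` (classifies the truth), `additive_noise` (adds
Gaussian error of sd `noise_sd` pollen/m³ to the concentration *before*
binning — noise lives in concentration space, mimicking a forecaster that
estimates a level and then bins it, which is what makes boundary
tolerances meaningful; label-space flips would not interact with
tolerances at all), `class_bias` (oracle label shifted by a fixed number
of classes, clamped), and `climatology` (a constant label). Each day is
independently replaced by a missing forecast with probability
`missing_prob`. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state is touched, and the label
noise is drawn before the missingness mask so outputs are bit-reproducible
per seed.

What the simulator does *not* emulate: weather-driven multi-day
autocorrelation of concentrations, bimodal or multi-taxon seasons, spatial
correlation between sites, and forecasters with state (e.g. persistence of
yesterday's class). Passing tests therefore demonstrate correctness of the
verification arithmetic and qualitative behaviour (tolerance monotonicity,
skill ordering, missingness accounting) — not that any real service scores
any particular number.

## Numerical choices

- Hit comparisons are plain float comparisons on the band edges; band
  arithmetic (`lower − t` floored at 0, `upper + t`) is exact for the
  one-decimal bands and tolerances in use.
- Season thresholds are computed as `pct/100 × realised annual index` and
  compared with ≥; ties on the cumulative sum resolve to the earlier day.
- Hit rates round half-to-even to one decimal (Python `round`), matching
  the usual table formatting.
- Ordinal forecast summaries code plain classes 0..k−1 in band order and
  intermediates at their pair midpoint; quartiles use midpoint
  interpolation so they land on labels or half-steps. Days without a
  forecast are excluded from quartiles/mean but counted under `NA`.
- Degenerate inputs raise typed errors rather than returning sentinels:
  an all-zero year (`DegenerateSeasonError`), a never-reached onset
  threshold (`NoEventError`), a window day without an observation
  (`InputError` naming the date), malformed files (`ParseError` naming
  file and line).

## Problem sizes in the test suite

The brute-force equivalence check runs 1000 random instances of 3–11 days
each; the Monte-Carlo recovery check verifies a 2000-day evaluation
against a 200 000-draw stand-alone estimate of the per-day hit
probability, at a 99% binomial interval. Both complete in seconds on one
CPU and are sized to make the binomial interval tight enough to detect a
scoring error of a few percentage points.

## Known limitations

- One taxon, one site per run; no cross-site pooling.
- Only today's forecast is evaluated; multi-day-ahead forecasts would need
  a lead-time dimension the input format does not carry.
- No skill scores beyond the hit rate (Heidke/Peirce skill, POD/FAR are
  natural extensions) and no significance tests between providers.
- The generator's parameters are plausible for temperate grass seasons but
  are not fitted to any station's climatology.
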