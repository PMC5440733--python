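# pollenverify

Verification of daily categorical pollen forecasts against measured pollen
concentrations.

Pollen services (websites, mobile apps, weather offices) publish the day's
allergen burden as a *load class* — no / low / moderate / high, sometimes
with intermediate steps such as "low-moderate" — while monitoring networks
measure the actual concentration in pollen grains per cubic meter with
volumetric (Hirst-type) traps. This package implements the evaluation
procedure that connects the two, for anyone auditing the quality of such a
forecast service: aerobiologists, pollen information services, and allergy
researchers.

## What it computes

**Load classification.** A configurable scheme maps concentrations to
classes. The default (four classes, as used by the Austrian pollen
information service) is, under a half-open convention:

| class    | band (pollen/m³) |
|----------|------------------|
| no       | [0, 1)           |
| low      | [1, 20)          |
| moderate | [20, 50)         |
| high     | [50, ∞)          |

Intermediate classes carry a numeric overlap interval centred on the pair's
boundary centre *c* with a ±20% span, `[0.8·c, 1.2·c]` where
`c = (lower bound of upper class) − 0.5`: low-moderate = [15.6, 23.4] and
moderate-high = [39.6, 59.4]. The no-low band [0, 2] is a configured
literal.

**Hit rates with boundary tolerance.** For each day *d* of the evaluation
window, a forecast label is a *hit* when the observed concentration lies in
the label's band widened symmetrically by a tolerance *t* ∈ {0, 2, 4}
pollen/m³ (floored at 0). The hit rate is

&nbsp;&nbsp;&nbsp;&nbsp;HR(t) = 100 · #{d : hit at tolerance t} / N,

with N either all window days (a missing forecast is a miss) or only days
with an available forecast — both denominators are implemented and always
recorded. With the overlap rule on, a plain forecast is also credited when
the observation falls in an adjacent (equally widened) intermediate
interval. HR(t) is non-decreasing in *t* by construction.

**Pollen season (1–95%).** The evaluation window is delineated from the
observations: the season runs from the first day the cumulative sum reaches
1% of the annual pollen index (the year's total) to the first day it
reaches 95%.

**Flowering onset.** A "readiness to flower" forecast date is verified
against the first day the observed load reaches moderate or higher; the
report is the signed offset in days (forecast − event).

**Synthetic data.** Because daily forecast archives are rarely published, a
simulator generates unimodal grass-pollen seasons (triangular weight curve,
lognormal day-to-day noise, target annual index) and forecasters of
controlled skill (oracle, additive concentration noise, class bias,
climatology, each with optional missing days), so the whole pipeline is
testable end to end.

## Worked example

Simulate a 2016 season and a noisy forecaster, then run the full report:

```sh
pollenverify simulate --seed 11 --forecaster additive_noise --noise-sd 5 \
    --missing-prob 0.1 --out-observations obs.tsv --out-forecasts fc.tsv
pollenverify report obs.tsv fc.tsv --seed 11 --out-dir out
```

`out/hit_rates.tsv` then contains (header comments abbreviated):

```
# denominator_mode: all_days
# tolerances: 0,2,4
# window: 2016-05-06..2016-07-28
app  window_start  window_end  n_days  n_available  availability_pct  n_correct_t0  hit_rate_t0  n_correct_t2  hit_rate_t2  n_correct_t4  hit_rate_t4
fc   2016-05-06    2016-07-28  84      73           86.9              69            82.1         69            82.1         71            84.5
```

Read: the 1–95% season spans 84 days; the forecaster was available on 73 of
them (86.9%); with missing days counted as misses it scored 82.1% exactly
and 84.5% with a ±4 pollen/m³ tolerance — non-decreasing in the tolerance,
as it must be. An onset check prints the signed offset directly:

```sh
$ pollenverify onset obs.tsv --forecast-date 2016-05-20
forecast        2016-05-20
event           2016-05-12
offset_days     +8
```

The same machinery is available as a library (`pollenverify.evaluate`,
`season_window`, `onset_offset`, `simulate_season`, ...); the CLI is a thin
wrapper over it.

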