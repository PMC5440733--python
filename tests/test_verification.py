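"""Hit-rate evaluation, availability accounting, forecast profiles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pollenverify as pv

# Default-scheme geometry, restated independently for the brute-force
# oracle: plain half-open bands and closed intermediate intervals.
PLAIN_BANDS = {"no": (0.0, 1.0), "low": (1.0, 20.0),
               "moderate": (20.0, 50.0), "high": (50.0, float("inf"))}
INTER_BANDS = {"no-low": (0.0, 2.0), "low-moderate": (15.6, 23.4),
               "moderate-high": (39.6, 59.4)}
NEIGHBOURS = {"no": ["no-low"], "low": ["no-low", "low-moderate"],
              "moderate": ["low-moderate", "moderate-high"],
              "high": ["moderate-high"]}


def oracle_hit(label, x, t, overlap):
    def in_plain(band):
        lo, hi = band
        return max(0.0, lo - t) <= x < hi + t

    def in_inter(band):
        lo, hi = band
        return max(0.0, lo - t) <= x <= hi + t

    if label in INTER_BANDS:
        return in_inter(INTER_BANDS[label])
    if in_plain(PLAIN_BANDS[label]):
        return True
    if overlap:
        return any(in_inter(INTER_BANDS[n]) for n in NEIGHBOURS[label])
    return False


def oracle_evaluate(labels, obs, t, mode, overlap):
    """Day-at-a-time reference scorer, independent of the package path."""
    n_days = len(labels)
    avail = [l for l in labels if l is not None]
    denom = n_days if mode == "all_days" else len(avail)
    n_correct = sum(1 for l, x in zip(labels, obs)
                    if l is not None and oracle_hit(l, x, t, overlap))
    return n_correct, round(100.0 * n_correct / denom, 1)


def make_pair(labels, obs, start="2016-06-01"):
    idx = pd.date_range(start, periods=len(labels))
    fc = pv.ForecastSeries(pd.Series(labels, index=idx, dtype=object),
                           app_name="test")
    series = pv.DailySeries(pd.Series(list(obs), index=idx, dtype=float))
    window = pv.SeasonWindow(idx[0].date(), idx[-1].date())
    return fc, series, window


def test_toy_five_day_exact_and_tolerant(scheme, toy_forecasts,
                                         toy_observations, toy_window):
    """Hand enumeration: (low,low,moderate,high,low) vs (5,25,30,12,19)
    scores 3/5 exact; at +/-4 with the overlap rule day 2 (25 in the
    expanded low-moderate interval) becomes a hit -> 4/5."""
    rep = pv.evaluate(toy_forecasts, toy_observations, toy_window, scheme)
    assert [r.hit_rate for r in rep.per_tolerance] == [60.0, 80.0, 80.0]
    assert [r.n_correct for r in rep.per_tolerance] == [3, 4, 4]
    rep_off = pv.evaluate(toy_forecasts, toy_observations, toy_window,
                          scheme, overlap_rule=False)
    assert [r.hit_rate for r in rep_off.per_tolerance] == [60.0, 60.0, 60.0]


def test_oracle_forecaster_scores_100(scheme):
    rng = np.random.default_rng(2)
    obs = rng.gamma(2.0, 15.0, size=40)
    labels = list(pv.classify_many(obs, scheme))
    fc, series, window = make_pair(labels, obs)
    rep = pv.evaluate(fc, series, window, scheme)
    assert all(r.hit_rate == 100.0 for r in rep.per_tolerance)


def test_disjoint_constant_forecast_scores_0(scheme):
    fc, series, window = make_pair(["no"] * 10, [55.0] * 10)
    rep = pv.evaluate(fc, series, window, scheme, tolerances=(0,))
    assert rep.per_tolerance[0].hit_rate == 0.0


def test_missing_days_denominator_modes(scheme):
    labels = ["low", None, "low", None, "low"]
    obs = [5.0, 5.0, 5.0, 5.0, 5.0]
    fc, series, window = make_pair(labels, obs)
    all_days = pv.evaluate(fc, series, window, scheme, tolerances=(0,),
                           denominator_mode="all_days")
    avail = pv.evaluate(fc, series, window, scheme, tolerances=(0,),
                        denominator_mode="available")
    assert all_days.n_available == avail.n_available == 3
    assert all_days.per_tolerance[0].hit_rate == 60.0
    assert avail.per_tolerance[0].hit_rate == 100.0


def test_evaluate_requires_observation_on_every_window_day(scheme):
    idx = pd.date_range("2016-06-01", periods=3)
    fc = pv.ForecastSeries(pd.Series(["low"] * 3, index=idx))
    series = pv.DailySeries(pd.Series([5.0, 5.0],
                                      index=idx[[0, 2]], dtype=float))
    window = pv.SeasonWindow(dt.date(2016, 6, 1), dt.date(2016, 6, 3))
    with pytest.raises(pv.InputError, match="2016-06-02"):
        pv.evaluate(fc, series, window, scheme)


def test_evaluate_requires_overlap_with_window(scheme):
    fc, series, _ = make_pair(["low"] * 3, [5.0] * 3)
    faraway = pv.SeasonWindow(dt.date(2016, 8, 1), dt.date(2016, 8, 3))
    series_aug = pv.DailySeries(pd.Series(
        [5.0] * 3, index=pd.date_range("2016-08-01", periods=3)))
    with pytest.raises(pv.InputError):
        pv.evaluate(fc, series_aug, faraway, scheme)


def test_evaluate_rejects_unsorted_tolerances(scheme, toy_forecasts,
                                              toy_observations, toy_window):
    with pytest.raises(pv.InputError):
        pv.evaluate(toy_forecasts, toy_observations, toy_window, scheme,
                    tolerances=(4, 2, 0))


label_strategy = st.one_of(
    st.none(),
    st.sampled_from(list(PLAIN_BANDS) + list(INTER_BANDS)))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(data=st.lists(
           st.tuples(label_strategy, st.floats(0, 80)),
           min_size=2, max_size=15),
       tol=st.sampled_from([0.0, 2.0, 4.0, 7.5]),
       mode=st.sampled_from(["all_days", "available"]),
       overlap=st.booleans())
def test_evaluate_matches_day_by_day_oracle(data, tol, mode, overlap):
    labels = [l for l, _ in data]
    obs = [x for _, x in data]
    if all(l is None for l in labels):
        return
    scheme = pv.default_scheme()
    fc, series, window = make_pair(labels, obs)
    rep = pv.evaluate(fc, series, window, scheme, tolerances=(tol,),
                      denominator_mode=mode, overlap_rule=overlap)
    exp_correct, exp_rate = oracle_evaluate(labels, obs, tol, mode, overlap)
    assert rep.per_tolerance[0].n_correct == exp_correct
    assert rep.per_tolerance[0].hit_rate == exp_rate


@settings(max_examples=100, derandomize=True, deadline=None)
@given(data=st.lists(
           st.tuples(label_strategy, st.floats(0, 80)),
           min_size=2, max_size=15))
def test_all_days_mode_never_beats_available(data):
    labels = [l for l, _ in data]
    obs = [x for _, x in data]
    if all(l is None for l in labels):
        return
    scheme = pv.default_scheme()
    fc, series, window = make_pair(labels, obs)
    kw = dict(tolerances=(0.0, 2.0, 4.0))
    rep_all = pv.evaluate(fc, series, window, scheme,
                          denominator_mode="all_days", **kw)
    rep_avail = pv.evaluate(fc, series, window, scheme,
                            denominator_mode="available", **kw)
    for a, b in zip(rep_all.per_tolerance, rep_avail.per_tolerance):
        assert a.hit_rate <= b.hit_rate
    # and hit rates never decrease with tolerance
    rates = [r.hit_rate for r in rep_all.per_tolerance]
    assert rates == sorted(rates)


def test_availability_counting(scheme):
    fc, _, window = make_pair(["low", None, "low", None, None,
                               "low", "low", None, "low", "low"],
                              [5.0] * 10)
    assert pv.availability(fc, window) == (10, 6, 0.6)
    full, _, w2 = make_pair(["low"] * 4, [5.0] * 4)
    assert pv.availability(full, w2)[2] == 1.0
    empty, _, w3 = make_pair([None] * 4, [5.0] * 4)
    assert pv.availability(empty, w3)[2] == 0.0


def test_profile_counts_and_ordinal_summary(scheme):
    fc, _, window = make_pair(["no", "no", "high", "high", None, None],
                              [0.0] * 6)
    prof = pv.forecast_profile(fc, window, scheme)
    assert prof.counts["no"] == prof.counts["high"] == 2
    assert prof.counts["NA"] == 2
    assert sum(prof.counts.values()) == window.n_days
    assert prof.mean == pytest.approx(1.5)  # codes 0,0,3,3
    assert prof.q50 == pytest.approx(1.5)


def test_profile_constant_forecast(scheme):
    fc, _, window = make_pair(["low"] * 7, [0.0] * 7)
    prof = pv.forecast_profile(fc, window, scheme)
    assert (prof.q25, prof.q50, prof.q75) == (1.0, 1.0, 1.0)
    assert prof.mean == 1.0


def test_profile_intermediate_at_midpoint(scheme):
    fc, _, window = make_pair(["low-moderate"] * 3, [0.0] * 3)
    prof = pv.forecast_profile(fc, window, scheme)
    assert prof.mean == pytest.approx(1.5)
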