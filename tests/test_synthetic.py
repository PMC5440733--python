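"""Simulated seasons and forecasters of controlled skill."""

import numpy as np
import pytest

import pollenverify as pv
from pollenverify.synthetic import FORECASTER_KINDS


def window_for(obs):
    return pv.season_window(obs)


def full_year_window(obs):
    dates = obs.dates
    return pv.SeasonWindow(dates[0], dates[-1])


def test_noiseless_curve_is_deterministic_and_on_target():
    cfg = pv.SeasonSimConfig(noise_sd_log=0.0, annual_index_target=1234.5)
    obs = pv.simulate_season(cfg)
    assert pv.annual_pollen_index(obs) == pytest.approx(1234.5, rel=1e-12)
    again = pv.simulate_season(cfg)
    assert np.array_equal(obs.values, again.values)


def test_same_seed_reproduces_series_different_seed_does_not():
    a = pv.simulate_season(pv.SeasonSimConfig(seed=5))
    b = pv.simulate_season(pv.SeasonSimConfig(seed=5))
    c = pv.simulate_season(pv.SeasonSimConfig(seed=6))
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_realized_index_matches_target_with_noise():
    obs = pv.simulate_season(pv.SeasonSimConfig(seed=1, noise_sd_log=0.8))
    assert pv.annual_pollen_index(obs) == pytest.approx(3000.0, rel=1e-9)


def test_season_window_falls_inside_simulated_support():
    cfg = pv.SeasonSimConfig(seed=2)
    obs = pv.simulate_season(cfg)
    w = pv.season_window(obs)
    start_doy = w.start.timetuple().tm_yday
    end_doy = w.end.timetuple().tm_yday
    assert cfg.season_start_doy - 10 <= start_doy
    assert end_doy <= cfg.season_end_doy + 10


def test_zero_outside_season():
    cfg = pv.SeasonSimConfig(seed=3)
    obs = pv.simulate_season(cfg)
    doy = np.arange(1, len(obs) + 1)
    outside = (doy < cfg.season_start_doy) | (doy > cfg.season_end_doy)
    assert np.all(obs.values[outside] == 0)
    assert np.all(obs.values[~outside][:5] > 0)


def test_config_validation():
    with pytest.raises(pv.InputError):
        pv.SeasonSimConfig(season_start_doy=200, season_peak_doy=150,
                           season_end_doy=230)
    with pytest.raises(pv.InputError):
        pv.SeasonSimConfig(annual_index_target=0)
    with pytest.raises(pv.InputError):
        pv.ForecasterSpec(kind="telepathy")
    with pytest.raises(pv.InputError):
        pv.ForecasterSpec(kind="climatology")  # needs fixed_label
    with pytest.raises(pv.InputError):
        pv.ForecasterSpec(missing_prob=1.5)


def test_oracle_forecaster_is_perfect(scheme):
    obs = pv.simulate_season(pv.SeasonSimConfig(seed=4))
    fc = pv.simulate_forecaster(obs, pv.ForecasterSpec(kind="oracle"), scheme)
    rep = pv.evaluate(fc, obs, window_for(obs), scheme)
    assert all(r.hit_rate == 100.0 for r in rep.per_tolerance)


def test_climatology_against_disjoint_truth(scheme, make_daily_series):
    obs = make_daily_series([60.0] * 30, start="2016-06-01")
    fc = pv.simulate_forecaster(
        obs, pv.ForecasterSpec(kind="climatology", fixed_label="no"), scheme)
    rep = pv.evaluate(fc, obs, full_year_window(obs), scheme,
                      tolerances=(0,))
    assert rep.per_tolerance[0].hit_rate == 0.0


def test_class_bias_shifts_and_clamps(scheme, make_daily_series):
    obs = make_daily_series([0.5, 5.0, 30.0, 70.0], start="2016-06-01")
    fc = pv.simulate_forecaster(
        obs, pv.ForecasterSpec(kind="class_bias", bias_classes=1), scheme)
    assert list(fc.data) == ["low", "moderate", "high", "high"]
    fc_down = pv.simulate_forecaster(
        obs, pv.ForecasterSpec(kind="class_bias", bias_classes=-2), scheme)
    assert list(fc_down.data) == ["no", "no", "no", "low"]


def test_forecaster_reproducible_under_seed(scheme):
    obs = pv.simulate_season(pv.SeasonSimConfig(seed=8))
    spec = pv.ForecasterSpec(kind="additive_noise", noise_sd=5,
                             missing_prob=0.2, seed=13)
    a = pv.simulate_forecaster(obs, spec, scheme)
    b = pv.simulate_forecaster(obs, spec, scheme)
    assert list(a.data) == list(b.data)


def test_missing_fraction_within_3_binomial_sd(scheme):
    obs = pv.simulate_season(pv.SeasonSimConfig(seed=10))
    p = 0.3
    fc = pv.simulate_forecaster(
        obs, pv.ForecasterSpec(kind="oracle", missing_prob=p, seed=21),
        scheme)
    n = len(fc)
    n_missing = sum(v is pv.MISSING for v in fc.data)
    sd = np.sqrt(p * (1 - p) * n)
    assert abs(n_missing - p * n) <= 3 * sd


def test_skill_ordering_oracle_beats_noisier_forecasters(scheme):
    """Expected hit rate decreases as forecast noise grows."""
    obs = pv.simulate_season(pv.SeasonSimConfig(
        seed=12, noise_sd_log=0.6, annual_index_target=4000))
    window = window_for(obs)
    rates = []
    for sd, seed in [(0.0, 31), (4.0, 32), (15.0, 33)]:
        fc = pv.simulate_forecaster(
            obs, pv.ForecasterSpec(kind="additive_noise", noise_sd=sd,
                                   seed=seed), scheme)
        rep = pv.evaluate(fc, obs, window, scheme, tolerances=(0,))
        rates.append(rep.per_tolerance[0].hit_rate)
    assert rates[0] == 100.0
    assert rates[0] > rates[1] > rates[2]


@pytest.mark.parametrize("kind,kw", [
    ("oracle", {}),
    ("additive_noise", {"noise_sd": 6.0}),
    ("class_bias", {"bias_classes": 2}),
    ("climatology", {"fixed_label": "low"}),
])
def test_every_forecaster_kind_is_tolerance_monotone(scheme, kind, kw):
    obs = pv.simulate_season(pv.SeasonSimConfig(seed=14))
    fc = pv.simulate_forecaster(
        obs, pv.ForecasterSpec(kind=kind, missing_prob=0.1, seed=15, **kw),
        scheme)
    rep = pv.evaluate(fc, obs, window_for(obs), scheme)
    rates = [r.hit_rate for r in rep.per_tolerance]
    assert rates == sorted(rates)


def test_forecaster_kind_registry_is_complete(scheme):
    obs = pv.simulate_season(pv.SeasonSimConfig(seed=16))
    for kind in FORECASTER_KINDS:
        kw = {"fixed_label": "no"} if kind == "climatology" else {}
        fc = pv.simulate_forecaster(obs, pv.ForecasterSpec(kind=kind, **kw),
                                    scheme)
        assert len(fc) == len(obs)
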