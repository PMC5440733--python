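import datetime as dt

import pandas as pd
import pytest

import pollenverify as pv


@pytest.fixture(scope="session")
def scheme():
    return pv.default_scheme()


@pytest.fixture()
def toy_window():
    return pv.SeasonWindow(dt.date(2016, 6, 1), dt.date(2016, 6, 5))


@pytest.fixture()
def toy_observations():
    idx = pd.date_range("2016-06-01", periods=5)
    return pv.DailySeries(pd.Series([5, 25, 30, 12, 19], index=idx,
                                    dtype=float), site="toy")


@pytest.fixture()
def toy_forecasts():
    idx = pd.date_range("2016-06-01", periods=5)
    return pv.ForecastSeries(
        pd.Series(["low", "low", "moderate", "high", "low"], index=idx),
        app_name="toy-app")


def make_series(values, start="2016-05-01", **kw):
    idx = pd.date_range(start, periods=len(values))
    return pv.DailySeries(pd.Series(list(values), index=idx, dtype=float),
                          **kw)


@pytest.fixture(scope="session")
def make_daily_series():
    return make_series
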