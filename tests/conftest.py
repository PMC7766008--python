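import numpy as np
import pandas as pd
import pytest

from hazemet.station_data import StationSeries, Variable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hourly_index():
    """Three full days of hourly timestamps."""
    return pd.date_range("2015-01-10", periods=72, freq="h")


def make_series(values, variable=Variable.T, station="M6", height=2.0,
                start="2015-01-10"):
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="h")
    return StationSeries.from_values(station, variable, height,
                                     pd.Series(values, index=idx))


@pytest.fixture
def make_hourly():
    return make_series
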