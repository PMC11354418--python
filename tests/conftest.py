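import datetime as dt

import numpy as np
import pytest

from cohortdd import DegreeDayParams, SimulationConfig, TemperatureSeries
from cohortdd.reference import reference_dataset


@pytest.fixture(scope="session")
def params():
    return DegreeDayParams()


@pytest.fixture
def constant_25(params):
    """60 days at a constant 25 degC: exactly 10 degree-days per day."""
    return TemperatureSeries(
        start=dt.date(2021, 4, 1), tmin=np.full(60, 25.0), tmax=np.full(60, 25.0)
    )


@pytest.fixture
def lab_series():
    """A long constant 18-25 degC series (6.5 degree-days per day)."""
    return TemperatureSeries(
        start=dt.date(2021, 1, 1), tmin=np.full(1400, 18.0), tmax=np.full(1400, 25.0)
    )


@pytest.fixture(scope="session")
def reference():
    """The deterministic benchmark rearing log and its temperature series."""
    records, series = reference_dataset()
    return records, series


@pytest.fixture
def small_config():
    return SimulationConfig(seed=123)


def random_series(rng, n_days=120, start=dt.date(2021, 1, 1)):
    """Seasonal-ish random temperature series for property tests."""
    mid = 21.5 + 3.0 * np.sin(np.linspace(0, 4 * np.pi, n_days)) + rng.normal(0, 1.5, n_days)
    half = rng.uniform(0.5, 4.0, n_days)
    return TemperatureSeries(start=start, tmin=mid - half, tmax=mid + half)
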