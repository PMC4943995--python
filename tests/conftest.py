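import datetime as dt

import pytest

from ddcohort import TemperatureDay, load_profile


@pytest.fixture(scope="session")
def profile():
    """Default D. suzukii profile: (VitalRateParams, ThermalThresholds)."""
    return load_profile("d_suzukii")


@pytest.fixture(scope="session")
def vr(profile):
    return profile[0]


@pytest.fixture(scope="session")
def thr(profile):
    return profile[1]


def make_day(tmin, tmax, date=dt.date(2013, 4, 1)):
    return TemperatureDay(date=date, tmin=tmin, tmax=tmax)


def constant_weather(start, n_days, tmin, tmax):
    """n contiguous identical days from start."""
    return [
        TemperatureDay(date=start + dt.timedelta(days=i), tmin=tmin, tmax=tmax)
        for i in range(n_days)
    ]
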