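"""Single sine degree-day computation and reproductive-threshold checks.

A day's physiological heat accumulation is estimated by fitting one sine
period to the day's minimum and maximum temperature and integrating the
area between the lower developmental threshold and the curve, with a
horizontal cutoff at the upper threshold.  The closed form below handles
all six classical interception cases (curve entirely below, within, or
above the thresholds, and the three intercepted geometries) in one
expression by clipping the arcsine arguments.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "TemperatureDay",
    "ThermalThresholds",
    "daily_dd_single_sine",
    "accumulate_dd",
    "reproduction_permitted",
]


@dataclass(frozen=True)
class TemperatureDay:
    """One day of weather: calendar date plus daily minimum / maximum air temperature (degC)."""

    date: dt.date
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tmin) and math.isfinite(self.tmax)):
            raise InvalidInputError(f"{self.date}: non-finite temperature")
        if self.tmin > self.tmax:
            raise InvalidInputError(
                f"{self.date}: tmin ({self.tmin}) exceeds tmax ({self.tmax})"
            )

    @property
    def mean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)


@dataclass(frozen=True)
class ThermalThresholds:
    """Developmental and reproductive temperature bounds (degC).

    Defaults are the D. suzukii values: development between 7.2 and 30,
    oviposition only between 13.4 and 29.3.  The reproductive band must
    sit inside the developmental band.
    """

    dev_low: float = 7.2
    dev_high: float = 30.0
    repro_low: float = 13.4
    repro_high: float = 29.3

    def __post_init__(self) -> None:
        if not self.dev_low < self.dev_high:
            raise InvalidInputError("dev_low must be below dev_high")
        if not self.repro_low < self.repro_high:
            raise InvalidInputError("repro_low must be below repro_high")
        if self.repro_low < self.dev_low or self.repro_high > self.dev_high:
            raise InvalidInputError(
                "reproductive interval must lie within the developmental interval"
            )


def daily_dd_single_sine(day: TemperatureDay, thr: ThermalThresholds | None = None) -> float:
    """Degree-days (degC * day) accumulated on one day, single sine method.

    The day's temperature trace is modelled as T(t) = m + A sin t over one
    period, with m the daily mean and A half the diurnal range.  The
    accumulation is the mean of clip(T, low, high) - low over the period
    (horizontal cutoff at the upper threshold), which reduces to

        DD = [ (m - L)(th2 - th1) + A(cos th1 - cos th2) + (U - L)(pi/2 - th2) ] / pi

    with th1 = arcsin(clip((L - m)/A)) and th2 = arcsin(clip((U - m)/A)),
    both in [-pi/2, pi/2].  Clipping the arcsine arguments collapses the
    six interception cases into this single expression.
    """
    thr = thr or ThermalThresholds()
    low, high = thr.dev_low, thr.dev_high
    m = day.mean
    amp = 0.5 * (day.tmax - day.tmin)

    if amp == 0.0:
        return max(0.0, min(m, high) - low)

    th1 = math.asin(min(1.0, max(-1.0, (low - m) / amp)))
    th2 = math.asin(min(1.0, max(-1.0, (high - m) / amp)))
    dd = (
        (m - low) * (th2 - th1)
        + amp * (math.cos(th1) - math.cos(th2))
        + (high - low) * (math.pi / 2.0 - th2)
    ) / math.pi
    # guard against tiny negative round-off when tmax is just above low
    return max(0.0, dd)


def _check_contiguous(series: Sequence[TemperatureDay]) -> None:
    for prev, cur in zip(series, series[1:]):
        gap = (cur.date - prev.date).days
        if gap == 0:
            raise InvalidInputError(f"duplicate date {cur.date} in weather series")
        if gap != 1:
            raise InvalidInputError(
                f"weather series gap: missing {prev.date + dt.timedelta(days=1)}"
            )
        if gap < 0:
            raise InvalidInputError("weather series not sorted by date")


def accumulate_dd(
    series: Iterable[TemperatureDay],
    thr: ThermalThresholds | None = None,
    start: dt.date | None = None,
) -> pd.DataFrame:
    """Daily and cumulative degree-days from ``start`` (default: first day).

    Returns a DataFrame with columns ``date``, ``daily_dd``, ``cum_dd``.
    The series must be sorted and contiguous; ``start`` must fall inside it.
    """
    days = list(series)
    if not days:
        raise InvalidInputError("empty weather series")
    _check_contiguous(days)
    if start is None:
        start = days[0].date
    if not (days[0].date <= start <= days[-1].date):
        raise InvalidInputError(f"start {start} outside weather series")
    days = [d for d in days if d.date >= start]
    daily = [daily_dd_single_sine(d, thr) for d in days]
    out = pd.DataFrame({"date": [d.date for d in days], "daily_dd": daily})
    out["cum_dd"] = out["daily_dd"].cumsum()
    return out


def reproduction_permitted(
    day: TemperatureDay,
    thr: ThermalThresholds | None = None,
    statistic: str = "mean",
) -> bool:
    """Whether oviposition is thermally permitted on this day.

    ``statistic='mean'`` (default) tests the daily mean against the
    reproductive band; ``'overlap'`` instead asks whether any part of the
    diurnal range overlaps the band.
    """
    thr = thr or ThermalThresholds()
    if statistic == "mean":
        return thr.repro_low <= day.mean <= thr.repro_high
    if statistic == "overlap":
        return day.tmax >= thr.repro_low and day.tmin <= thr.repro_high
    raise InvalidInputError(f"unknown reproduction statistic {statistic!r}")
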