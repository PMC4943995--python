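"""Seeded synthetic inputs: weather series, life tables, dissection
surveys, and a stochastic individual-based oracle population.

The weather generator produces a temperate annual cycle — an annual
sinusoid in the daily mean, a fixed diurnal range, and Gaussian daily
noise.  Two presets bracket the two study climates:

``salem_like``
    A cool maritime season (Willamette-Valley-like): degree-days begin
    accumulating in early March and summer means stay inside the
    reproductive band, so season-long parasitism scenarios run
    uninterrupted.
``parlier_like``
    A hot interior-valley season (San-Joaquin-like): warm from April,
    with a mid-summer stretch whose daily means exceed the 29.3 degC
    reproductive ceiling — the hot period during which oviposition
    shuts down.

The individual-based simulator mirrors the cohort model's daily update
exactly, but with integer individuals: binomial survival thinning at
the same conditional-survival probabilities and Poisson recruitment at
the same expected fecundity.  Its replicate mean is therefore an
independent oracle for the deterministic cohort trajectories.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .degree_days import (
    TemperatureDay,
    ThermalThresholds,
    daily_dd_single_sine,
    reproduction_permitted,
)
from .errors import InvalidInputError
from .maturity import DissectionRecord, MaturityRegression
from .vital_rates import GompertzParams, VitalRateParams, maternity_dd, survival_dd

__all__ = [
    "WeatherGenSpec",
    "gen_weather",
    "salem_like",
    "parlier_like",
    "gen_survival_table",
    "gen_dissection_table",
    "simulate_individuals",
]


@dataclass(frozen=True)
class WeatherGenSpec:
    """Parameters of the synthetic annual temperature cycle."""

    start: dt.date
    end: dt.date
    annual_mean: float = 12.0  # degC
    annual_amplitude: float = 9.0  # degC, half peak-to-trough of the seasonal cycle
    phase_day: int = 110  # day-of-year at which the sinusoid crosses its mean rising
    diurnal_range: float = 12.0  # degC between tmin and tmax
    noise_sd: float = 1.5  # degC daily Gaussian noise on the mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidInputError("end date before start date")
        if self.diurnal_range < 0 or self.noise_sd < 0:
            raise InvalidInputError("diurnal_range and noise_sd must be non-negative")


def gen_weather(spec: WeatherGenSpec) -> list[TemperatureDay]:
    """Generate a contiguous daily weather series; same seed, same series."""
    rng = np.random.default_rng(spec.seed)
    n = (spec.end - spec.start).days + 1
    days = []
    for i in range(n):
        date = spec.start + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        tmean = (
            spec.annual_mean
            + spec.annual_amplitude * math.sin(2.0 * math.pi * (doy - spec.phase_day) / 365.0)
            + rng.normal(0.0, spec.noise_sd)
        )
        half = 0.5 * spec.diurnal_range
        days.append(TemperatureDay(date=date, tmin=tmean - half, tmax=tmean + half))
    return days


def salem_like(year: int = 2013, seed: int = 0) -> WeatherGenSpec:
    """Cool maritime full-year preset (see module docstring)."""
    return WeatherGenSpec(
        start=dt.date(year, 1, 1),
        end=dt.date(year, 12, 31),
        annual_mean=11.5,
        annual_amplitude=8.5,
        phase_day=105,
        diurnal_range=12.0,
        noise_sd=1.5,
        seed=seed,
    )


def parlier_like(year: int = 2013, seed: int = 0) -> WeatherGenSpec:
    """Hot interior-valley full-year preset (see module docstring)."""
    return WeatherGenSpec(
        start=dt.date(year, 1, 1),
        end=dt.date(year, 12, 31),
        annual_mean=17.5,
        annual_amplitude=12.5,
        phase_day=110,
        diurnal_range=15.0,
        noise_sd=1.5,
        seed=seed,
    )


def gen_survival_table(
    params: GompertzParams,
    ages,
    n0: int,
    seed: int = 0,
    noise: bool = True,
) -> pd.DataFrame:
    """Synthetic life table: survivors of an initial cohort of ``n0`` at
    each age.

    With ``noise`` the count at age x is Binomial(n0, L(x)) — independent
    per age, emulating destructive subsampling; without it the exact
    expectation n0 * L(x).  Columns: ``age``, ``n_alive``, ``fraction``.
    """
    if n0 <= 0:
        raise InvalidInputError("n0 must be positive")
    ages = np.asarray(ages, dtype=float)
    lx = survival_dd(ages, params)
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.binomial(n0, lx).astype(float)
        counts[ages == 0] = n0  # the cohort is fully observed at age 0
    else:
        counts = n0 * lx
    return pd.DataFrame({"age": ages, "n_alive": counts, "fraction": counts / n0})


def gen_dissection_table(
    true_model: MaturityRegression,
    dd_points,
    n_per_point: int,
    seed: int = 0,
    region: str = "synthetic",
) -> list[DissectionRecord]:
    """Synthetic dissection survey: mature counts are Binomial(n, p) with
    p the true line's prediction clipped to [0, 100], as a proportion."""
    if n_per_point <= 0:
        raise InvalidInputError("n_per_point must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for ddm in dd_points:
        p = min(100.0, max(0.0, true_model.slope * ddm + true_model.intercept)) / 100.0
        k = int(rng.binomial(n_per_point, p))
        records.append(
            DissectionRecord(
                region=region, dd_midpoint=float(ddm), n_dissected=n_per_point, n_mature=k
            )
        )
    return records


def simulate_individuals(
    weather,
    start: dt.date,
    end: dt.date,
    n0: int,
    init_age: float,
    vr: VitalRateParams | None = None,
    thr: ThermalThresholds | None = None,
    seed: int = 0,
    female_fraction: float = 1.0,
) -> np.ndarray:
    """Stochastic individual-based run; returns the daily total population.

    Individuals born the same day are exchangeable, so each birth cohort
    is stored as an integer count; daily survival is a Binomial thinning
    at the cohort's conditional-survival probability (equivalent to
    independent per-individual Bernoulli survival) and recruitment is
    Poisson with mean equal to the day's expected net maternity.  The
    update order matches the deterministic model, so the replicate mean
    is an unbiased oracle for it.
    """
    vr = vr or VitalRateParams()
    thr = thr or ThermalThresholds()
    rng = np.random.default_rng(seed)
    by_date = {d.date: d for d in weather}
    n_days = (end - start).days + 1
    cohorts: list[list] = [[init_age, int(n0)]]  # [age, count]
    totals = np.zeros(n_days)
    for i in range(n_days):
        date = start + dt.timedelta(days=i)
        if date not in by_date:
            raise InvalidInputError(f"weather series missing {date}")
        day = by_date[date]
        ddelta = daily_dd_single_sine(day, thr)
        repro_ok = reproduction_permitted(day, thr)
        expected_eggs = 0.0
        survivors = []
        for age, count in cohorts:
            if ddelta > 0.0 and count > 0:
                p = survival_dd(age + ddelta, vr.survival_dd) / survival_dd(age, vr.survival_dd)
                count = int(rng.binomial(count, min(1.0, p)))
            if (
                repro_ok
                and ddelta > 0.0
                and vr.maternity.support_lo <= age < vr.maternity.support_hi
            ):
                expected_eggs += count * maternity_dd(age + 0.5 * ddelta, vr.maternity) * ddelta
            age += ddelta
            if age < vr.stages.adult_end and count > 0:
                survivors.append([age, count])
        expected_eggs *= female_fraction
        if expected_eggs > 0.0:
            born = int(rng.poisson(expected_eggs))
            if born > 0:
                survivors.append([0.0, born])
        cohorts = survivors
        totals[i] = sum(c[1] for c in cohorts)
    return totals
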