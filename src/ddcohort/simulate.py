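"""Daily-step, degree-day-indexed cohort population model.

Each cohort is a group born on the same day, tracked by a shared
physiological age chi (cumulative DD since birth) and an abundance of
females.  One simulated day proceeds as:

1. compute the day's degree-days (single sine);
2. apply management mortality (scenario multipliers per stage,
   including the one-off parasitism hit when a cohort crosses the
   larva-to-pupa boundary);
3. apply natural survival via the conditional Gompertz survivorship
   L(x + dDD) / L(x);
4. if the day's mean temperature sits inside the reproductive band,
   accumulate net maternity  sum_cohorts size * M(x + dDD/2) * dDD
   (midpoint rule) scaled by any fecundity/viability multipliers — the
   sum recruits a new cohort aged 0 DD;
5. age every cohort by the day's DD;
6. drop cohorts that have reached the maximum adult age or fallen
   below the extinction threshold.

The model is deterministic: there is no randomness in the core.  On a
day with zero DD nothing ages, dies, or reproduces (extreme-temperature
mortality is deliberately outside the seasonal model).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .degree_days import (
    TemperatureDay,
    ThermalThresholds,
    daily_dd_single_sine,
    reproduction_permitted,
)
from .errors import InvalidInputError
from .management import ManagementScenario
from .vital_rates import Stage, VitalRateParams, conditional_survival, maternity_dd, stage_of

__all__ = [
    "Cohort",
    "PopulationState",
    "SimulationResult",
    "step_day",
    "run_simulation",
    "relative_impact",
    "default_initial_cohorts",
]

_STAGE_COLS = ["egg", "larva", "pupa", "adult"]


@dataclass
class Cohort:
    """A same-day birth cohort: DD age and female abundance."""

    birth_date: dt.date
    age: float
    size: float
    initial_size: float

    def __post_init__(self) -> None:
        if self.age < 0 or self.size < 0 or self.initial_size < 0:
            raise InvalidInputError("cohort age and sizes must be non-negative")


@dataclass
class PopulationState:
    date: dt.date
    cohorts: list[Cohort] = field(default_factory=list)
    cumulative_dd: float = 0.0

    @property
    def total(self) -> float:
        return sum(c.size for c in self.cohorts)

    def stage_totals(self, stages) -> dict[str, float]:
        out = dict.fromkeys(_STAGE_COLS, 0.0)
        for c in self.cohorts:
            st = stage_of(c.age, stages)
            if st is not Stage.DEAD:
                out[st.value] += c.size
        return out


@dataclass
class SimulationResult:
    """One row per simulated day: DD, abundance by stage, recruitment."""

    table: pd.DataFrame
    label: str = "control"

    def final_total(self) -> float:
        return float(self.table["total"].iloc[-1]) if len(self.table) else 0.0


def default_initial_cohorts(start: dt.date, size: float = 100.0, age: float = 200.0) -> list[Cohort]:
    """Season-start population: one adult cohort (overwintered adults)."""
    return [Cohort(birth_date=start, age=age, size=size, initial_size=size)]


def step_day(
    state: PopulationState,
    day: TemperatureDay,
    vr: VitalRateParams,
    thr: ThermalThresholds,
    mgmt: ManagementScenario | None = None,
    extinction_threshold: float = 0.0,
    female_fraction: float = 1.0,
) -> tuple[PopulationState, dict]:
    """Advance the population by one day; returns (new state, day record)."""
    if day.date != state.date + dt.timedelta(days=1):
        raise InvalidInputError(
            f"weather day {day.date} does not follow state date {state.date}"
        )
    ddelta = daily_dd_single_sine(day, thr)
    repro_ok = reproduction_permitted(day, thr)
    eggs = 0.0
    survivors: list[Cohort] = []
    for c in state.cohorts:
        size = c.size
        if mgmt is not None:
            crossing = c.age < vr.stages.larva_end <= c.age + ddelta
            surv_m, fec_m, viab_m = mgmt.daily_multipliers(
                day.date, stage_of(c.age, vr.stages), crossing_pupation=crossing
            )
            size *= surv_m
        else:
            fec_m = viab_m = 1.0
        if ddelta > 0.0:
            size *= conditional_survival(c.age, ddelta, vr.survival_dd)
        if (
            repro_ok
            and ddelta > 0.0
            and vr.maternity.support_lo <= c.age < vr.maternity.support_hi
        ):
            eggs += size * maternity_dd(c.age + 0.5 * ddelta, vr.maternity) * ddelta * fec_m * viab_m
        new_age = c.age + ddelta
        if new_age < vr.stages.adult_end and size >= extinction_threshold and size > 0.0:
            survivors.append(replace(c, age=new_age, size=size))
    eggs *= female_fraction
    if eggs > 0.0:
        survivors.append(
            Cohort(birth_date=day.date, age=0.0, size=eggs, initial_size=eggs)
        )
    new_state = PopulationState(
        date=day.date, cohorts=survivors, cumulative_dd=state.cumulative_dd + ddelta
    )
    record = {
        "date": day.date,
        "daily_dd": ddelta,
        "cum_dd": new_state.cumulative_dd,
        **new_state.stage_totals(vr.stages),
        "total": new_state.total,
        "new_eggs": eggs,
    }
    return new_state, record


def run_simulation(
    weather,
    start: dt.date,
    end: dt.date,
    init: list[Cohort] | None = None,
    vr: VitalRateParams | None = None,
    thr: ThermalThresholds | None = None,
    mgmt: ManagementScenario | None = None,
    female_fraction: float = 1.0,
    extinction_rel_threshold: float = 1e-9,
    label: str | None = None,
) -> SimulationResult:
    """Run the cohort model over [start, end] on a daily weather series.

    ``init`` defaults to one overwintered adult cohort of 100 females at
    age 200 DD.  Cohorts smaller than ``extinction_rel_threshold`` times
    the initial total are culled.  Deterministic given its inputs.
    """
    vr = vr or VitalRateParams()
    thr = thr or ThermalThresholds()
    if end < start:
        raise InvalidInputError("end date before start date")
    by_date = {d.date: d for d in weather}
    n_days = (end - start).days + 1
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    missing = [d for d in dates if d not in by_date]
    if missing:
        raise InvalidInputError(f"weather series missing {missing[0]}")
    if init is None:
        init = default_initial_cohorts(start)
    init = [replace(c) for c in init]
    ext = extinction_rel_threshold * sum(c.size for c in init)
    state = PopulationState(date=start - dt.timedelta(days=1), cohorts=init)
    records = []
    for d in dates:
        state, rec = step_day(
            state,
            by_date[d],
            vr,
            thr,
            mgmt=mgmt,
            extinction_threshold=ext,
            female_fraction=female_fraction,
        )
        records.append(rec)
    table = pd.DataFrame(records, columns=["date", "daily_dd", "cum_dd", *_STAGE_COLS, "total", "new_eggs"])
    if label is None:
        label = mgmt.label if mgmt is not None else "control"
    return SimulationResult(table=table, label=label)


def relative_impact(treated: SimulationResult, control: SimulationResult) -> pd.DataFrame:
    """Per-day treated/control total-population ratio and percent reduction.

    Days where the control total is zero are flagged (``undefined`` True,
    ratio NaN) rather than raising.
    """
    t, c = treated.table, control.table
    if len(t) != len(c) or not (t["date"].values == c["date"].values).all():
        raise InvalidInputError("treated and control runs cover different dates")
    ctrl = c["total"].to_numpy(dtype=float)
    trt = t["total"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ctrl > 0, trt / ctrl, np.nan)
    out = pd.DataFrame(
        {
            "date": t["date"],
            "control_total": ctrl,
            "treated_total": trt,
            "ratio": ratio,
            "percent_reduction": 100.0 * (1.0 - ratio),
            "undefined": ctrl <= 0,
        }
    )
    return out
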