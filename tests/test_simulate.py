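"""Cohort simulator: single-day mechanics, whole runs, and the
individual-based stochastic oracle."""

import datetime as dt

import numpy as np
import pytest

from ddcohort import (
    Cohort,
    InvalidInputError,
    PopulationState,
    TemperatureDay,
    conditional_survival,
    daily_dd_single_sine,
    gen_weather,
    make_null,
    maternity_dd,
    relative_impact,
    run_simulation,
    salem_like,
    simulate_individuals,
    step_day,
    survival_dd,
)

from conftest import constant_weather

START = dt.date(2013, 4, 1)


def adult_cohort(size=100.0, age=200.0, date=START):
    return Cohort(birth_date=date, age=age, size=size, initial_size=size)


def state_with(cohorts, date=START - dt.timedelta(days=1)):
    return PopulationState(date=date, cohorts=list(cohorts))


class TestStepDay:
    def test_zero_dd_day_is_inert(self, vr, thr):
        cold = TemperatureDay(date=START, tmin=-2.0, tmax=5.0)
        state = state_with([adult_cohort(age=400.0)])
        new, rec = step_day(state, cold, vr, thr)
        assert rec["daily_dd"] == 0.0
        assert rec["new_eggs"] == 0.0
        assert new.cohorts[0].age == 400.0
        assert new.cohorts[0].size == 100.0

    def test_reproducing_adult_cohort_hand_computed(self, vr, thr):
        # warm day: mean 17.2 -> permitted; dd computed below
        day = TemperatureDay(date=START, tmin=12.2, tmax=22.2)
        dd = daily_dd_single_sine(day, thr)
        state = state_with([adult_cohort(size=50.0, age=400.0)])
        new, rec = step_day(state, day, vr, thr)
        size_after = 50.0 * conditional_survival(400.0, dd, vr.survival_dd)
        expected_eggs = size_after * maternity_dd(400.0 + dd / 2.0, vr.maternity) * dd
        assert rec["new_eggs"] == pytest.approx(expected_eggs)
        ages = sorted(c.age for c in new.cohorts)
        assert ages == pytest.approx([0.0, 400.0 + dd])

    def test_larval_cohort_never_reproduces(self, vr, thr):
        day = TemperatureDay(date=START, tmin=15.0, tmax=25.0)
        state = state_with([Cohort(birth_date=START, age=100.0, size=40.0, initial_size=40.0)])
        _, rec = step_day(state, day, vr, thr)
        assert rec["new_eggs"] == 0.0

    def test_cohort_culled_at_max_age(self, vr, thr):
        day = TemperatureDay(date=START, tmin=15.0, tmax=25.0)
        state = state_with([adult_cohort(age=605.0)])
        new, _ = step_day(state, day, vr, thr)
        assert all(c.age < vr.stages.adult_end for c in new.cohorts)

    def test_non_consecutive_date_rejected(self, vr, thr):
        day = TemperatureDay(date=START + dt.timedelta(days=5), tmin=10, tmax=20)
        with pytest.raises(InvalidInputError):
            step_day(state_with([adult_cohort()]), day, vr, thr)


class TestRunSimulation:
    def test_empty_population_stays_empty(self, vr, thr):
        w = constant_weather(START, 20, 12.0, 22.0)
        res = run_simulation(w, START, START + dt.timedelta(days=19), init=[], vr=vr, thr=thr)
        assert (res.table["total"] == 0.0).all()
        assert (res.table["new_eggs"] == 0.0).all()

    def test_cold_run_only_declines(self, vr, thr):
        # DD accumulate but the mean (10 degC) is below the reproductive floor
        w = constant_weather(START, 30, 5.0, 15.0)
        res = run_simulation(
            w, START, START + dt.timedelta(days=29), init=[adult_cohort()], vr=vr, thr=thr
        )
        assert (res.table["new_eggs"] == 0.0).all()
        totals = res.table["total"].to_numpy()
        assert np.all(np.diff(totals) <= 1e-12)
        assert totals[-1] <= 100.0

    def test_pure_decay_matches_survivorship_ratio(self, vr, thr):
        # conservation oracle: with no recruitment the trajectory is
        # initial_size * L(age) / L(age0)
        w = constant_weather(START, 25, 5.0, 15.0)
        dd = daily_dd_single_sine(w[0], thr)
        res = run_simulation(
            w, START, START + dt.timedelta(days=24),
            init=[adult_cohort(size=100.0, age=250.0)], vr=vr, thr=thr,
            extinction_rel_threshold=0.0,
        )
        for i, total in enumerate(res.table["total"]):
            age = 250.0 + (i + 1) * dd
            expected = 100.0 * survival_dd(age, vr.survival_dd) / survival_dd(250.0, vr.survival_dd)
            assert total == pytest.approx(expected, rel=1e-9)

    def test_stage_composition_starts_all_adult(self, vr, thr):
        w = constant_weather(START, 30, 12.0, 22.0)
        res = run_simulation(
            w, START, START + dt.timedelta(days=29), init=[adult_cohort()], vr=vr, thr=thr
        )
        first = res.table.iloc[0]
        assert first["adult"] == pytest.approx(first["total"])
        # once oviposition starts, the adult fraction falls below 1
        later = res.table.iloc[-1]
        assert later["egg"] > 0.0
        assert later["adult"] / later["total"] < 1.0

    def test_column_sums_consistent(self, vr, thr):
        w = constant_weather(START, 40, 12.0, 24.0)
        res = run_simulation(
            w, START, START + dt.timedelta(days=39), init=[adult_cohort()], vr=vr, thr=thr
        )
        stage_sum = res.table[["egg", "larva", "pupa", "adult"]].sum(axis=1)
        assert np.allclose(stage_sum, res.table["total"])

    def test_deterministic(self, vr, thr):
        w = gen_weather(salem_like(seed=7))
        a = run_simulation(w, START, START + dt.timedelta(days=40), vr=vr, thr=thr)
        b = run_simulation(w, START, START + dt.timedelta(days=40), vr=vr, thr=thr)
        assert a.table.equals(b.table)

    def test_missing_weather_rejected(self, vr, thr):
        w = constant_weather(START, 5, 10.0, 20.0)
        with pytest.raises(InvalidInputError, match="missing"):
            run_simulation(w, START, START + dt.timedelta(days=10), vr=vr, thr=thr)

    def test_half_day_split_consistency(self, vr, thr):
        # splitting a day's DD into two half-increments leaves
        # survivorship unchanged (telescoping conditional survival)
        dd = 8.0
        size = 123.0
        age = 300.0
        one = size * conditional_survival(age, dd, vr.survival_dd)
        half = size * conditional_survival(age, dd / 2, vr.survival_dd)
        two = half * conditional_survival(age + dd / 2, dd / 2, vr.survival_dd)
        assert two == pytest.approx(one, rel=1e-12)


class TestRelativeImpact:
    def test_null_scenario_ratio_is_one(self, vr, thr):
        w = constant_weather(START, 30, 12.0, 22.0)
        end = START + dt.timedelta(days=29)
        ctrl = run_simulation(w, START, end, init=[adult_cohort()], vr=vr, thr=thr)
        null = run_simulation(
            w, START, end, init=[adult_cohort()], vr=vr, thr=thr, mgmt=make_null()
        )
        ri = relative_impact(null, ctrl)
        assert np.allclose(ri["ratio"], 1.0)
        assert null.table.equals(ctrl.table.assign())

    def test_control_zero_is_flagged_not_raised(self, vr, thr):
        w = constant_weather(START, 5, 12.0, 22.0)
        end = START + dt.timedelta(days=4)
        empty = run_simulation(w, START, end, init=[], vr=vr, thr=thr)
        ri = relative_impact(empty, empty)
        assert ri["undefined"].all()
        assert ri["ratio"].isna().all()

    def test_mismatched_dates_rejected(self, vr, thr):
        w = constant_weather(START, 10, 12.0, 22.0)
        a = run_simulation(w, START, START + dt.timedelta(days=5), vr=vr, thr=thr)
        b = run_simulation(w, START, START + dt.timedelta(days=9), vr=vr, thr=thr)
        with pytest.raises(InvalidInputError):
            relative_impact(a, b)


class TestIndividualBasedOracle:
    def test_cohort_model_matches_ibm_mean(self, vr, thr):
        """Deterministic totals sit within Monte-Carlo error of the mean of
        stochastic individual-based replicates (same rates, integer
        individuals, binomial thinning, Poisson recruitment)."""
        w = gen_weather(salem_like(seed=3))
        start, n_days = dt.date(2013, 4, 1), 30
        end = start + dt.timedelta(days=n_days - 1)
        init = [Cohort(birth_date=start, age=200.0, size=200.0, initial_size=200.0)]
        det = run_simulation(
            w, start, end, init=init, vr=vr, thr=thr, extinction_rel_threshold=0.0
        )
        reps = np.array(
            [
                simulate_individuals(w, start, end, 200, 200.0, vr, thr, seed=s)
                for s in range(60)
            ]
        )
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        totals = det.table["total"].to_numpy()
        ok = se > 0
        assert np.all(np.abs(totals[ok] - mean[ok]) <= 3.0 * se[ok])
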