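"""Validated readers/writers for the package's CSV and YAML dialects.

Weather CSV: header ``date,tmin,tmax``, ISO-8601 dates, degC, contiguous
dates.  Dissection CSV: ``region,dd_midpoint,n_dissected,n_mature``.
Simulation results round-trip through CSV at full precision.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd
import yaml

from .degree_days import TemperatureDay
from .errors import InvalidInputError
from .management import BUILTIN_SCENARIOS, Intervention, ManagementScenario
from .maturity import DissectionRecord
from .simulate import Cohort, SimulationResult

__all__ = [
    "read_weather",
    "write_weather",
    "read_dissections",
    "write_result",
    "read_result",
    "read_scenario",
    "load_run_config",
]

_RESULT_COLS = ["date", "daily_dd", "cum_dd", "egg", "larva", "pupa", "adult", "total", "new_eggs"]


def _parse_date(value, context: str) -> dt.date:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise InvalidInputError(f"{context}: bad date {value!r}") from exc


def read_weather(path) -> list[TemperatureDay]:
    """Read a weather CSV; rejects gaps, duplicates, and tmin > tmax."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise InvalidInputError(f"weather file not found: {path}") from exc
    missing = {"date", "tmin", "tmax"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    days = []
    prev: dt.date | None = None
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        date = _parse_date(row.date, f"{path} line {i}")
        try:
            day = TemperatureDay(date=date, tmin=float(row.tmin), tmax=float(row.tmax))
        except (InvalidInputError, ValueError) as exc:
            raise InvalidInputError(f"{path} line {i}: {exc}") from exc
        if prev is not None:
            gap = (date - prev).days
            if gap == 0:
                raise InvalidInputError(f"{path} line {i}: duplicate date {date}")
            if gap != 1:
                raise InvalidInputError(
                    f"{path} line {i}: missing date {prev + dt.timedelta(days=1)}"
                )
        prev = date
        days.append(day)
    if not days:
        raise InvalidInputError(f"{path}: empty weather file")
    return days


def write_weather(days: list[TemperatureDay], path) -> None:
    pd.DataFrame(
        {"date": [d.date.isoformat() for d in days],
         "tmin": [d.tmin for d in days],
         "tmax": [d.tmax for d in days]}
    ).to_csv(path, index=False)


def read_dissections(path) -> list[DissectionRecord]:
    """Read a dissection-survey CSV."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise InvalidInputError(f"dissection file not found: {path}") from exc
    missing = {"region", "dd_midpoint", "n_dissected", "n_mature"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                DissectionRecord(
                    region=str(row.region),
                    dd_midpoint=float(row.dd_midpoint),
                    n_dissected=int(row.n_dissected),
                    n_mature=int(row.n_mature),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            raise InvalidInputError(f"{path} line {i}: {exc}") from exc
    return records


def write_result(result: SimulationResult, path) -> None:
    """Write a simulation result CSV (full float precision round-trip)."""
    out = result.table.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False, float_format="%.17g")


def read_result(path, label: str | None = None) -> SimulationResult:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError as exc:
        raise InvalidInputError(f"result file not found: {path}") from exc
    missing = set(_RESULT_COLS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    df["date"] = df["date"].map(lambda v: _parse_date(v, str(path)))
    return SimulationResult(table=df[_RESULT_COLS], label=label or Path(path).stem)


def read_scenario(name_or_path: str, application_date: dt.date | None = None) -> ManagementScenario:
    """A built-in scenario name, or a YAML file of intervention mappings."""
    if name_or_path in BUILTIN_SCENARIOS:
        factory = BUILTIN_SCENARIOS[name_or_path]
        if name_or_path.startswith("insecticide"):
            if application_date is None:
                raise InvalidInputError(
                    f"scenario {name_or_path!r} requires an application date"
                )
            return factory(application_date)
        return factory()
    path = Path(name_or_path)
    if not path.exists():
        raise InvalidInputError(f"unknown scenario {name_or_path!r}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "interventions" not in data:
        raise InvalidInputError(f"{path}: scenario file needs a top-level 'interventions' list")
    interventions = []
    for spec in data["interventions"]:
        spec = dict(spec)
        if "application_date" in spec and spec["application_date"] is not None:
            spec["application_date"] = _parse_date(spec["application_date"], str(path))
        try:
            interventions.append(Intervention(**spec))
        except (InvalidInputError, TypeError) as exc:
            raise InvalidInputError(f"{path}: bad intervention: {exc}") from exc
    return ManagementScenario(label=data.get("label", path.stem), interventions=interventions)


def load_run_config(path) -> dict:
    """Load and validate a simulation run config (YAML).

    Keys: weather (path, required), start, end (dates, required),
    profile (default d_suzukii), scenario (name/path, optional),
    application_date (for built-in insecticides), initial (list of
    {age, size}), label, female_fraction, output.
    """
    p = Path(path)
    if not p.exists():
        raise InvalidInputError(f"config file not found: {path}")
    cfg = yaml.safe_load(p.read_text())
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")
    for key in ("weather", "start", "end"):
        if key not in cfg:
            raise InvalidInputError(f"{path}: missing required key {key!r}")
    weather_path = (p.parent / cfg["weather"]).resolve() if not Path(cfg["weather"]).is_absolute() else Path(cfg["weather"])
    if not weather_path.exists():
        raise InvalidInputError(f"{path}: weather file {weather_path} does not exist")
    out = {
        "weather": weather_path,
        "start": _parse_date(cfg["start"], str(path)),
        "end": _parse_date(cfg["end"], str(path)),
        "profile": cfg.get("profile", "d_suzukii"),
        "scenario": cfg.get("scenario"),
        "application_date": (
            _parse_date(cfg["application_date"], str(path))
            if cfg.get("application_date") is not None
            else None
        ),
        "label": cfg.get("label"),
        "female_fraction": float(cfg.get("female_fraction", 1.0)),
        "output": cfg.get("output"),
        "initial": None,
    }
    if "initial" in cfg and cfg["initial"] is not None:
        initial = []
        for item in cfg["initial"]:
            try:
                size = float(item["size"])
                age = float(item.get("age", 0.0))
            except (KeyError, TypeError, ValueError) as exc:
                raise InvalidInputError(f"{path}: bad initial cohort {item!r}") from exc
            initial.append(
                Cohort(birth_date=out["start"], age=age, size=size, initial_size=size)
            )
        out["initial"] = initial
    return out
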