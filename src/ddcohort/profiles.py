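"""Species-profile loading: thresholds, stage table, and curve parameters.

A profile is a YAML mapping (see ``data/d_suzukii.yaml``).  ``load_profile``
accepts either a built-in profile name or a path to a user file.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .degree_days import ThermalThresholds
from .errors import InvalidInputError
from .vital_rates import CauchyParams, GompertzParams, StageTable, VitalRateParams

__all__ = ["load_profile", "profile_dict", "BUILTIN_PROFILES"]

BUILTIN_PROFILES = ("d_suzukii",)


def profile_dict(name_or_path: str = "d_suzukii") -> dict:
    """Raw profile mapping, from a built-in name or a YAML file path."""
    if name_or_path in BUILTIN_PROFILES:
        text = (
            importlib.resources.files("ddcohort.data")
            .joinpath(f"{name_or_path}.yaml")
            .read_text()
        )
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise InvalidInputError(f"unknown profile {name_or_path!r}")
        text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidInputError(f"profile {name_or_path!r} is not a mapping")
    return data


def load_profile(name_or_path: str = "d_suzukii") -> tuple[VitalRateParams, ThermalThresholds]:
    """Build (VitalRateParams, ThermalThresholds) from a profile."""
    data = profile_dict(name_or_path)
    try:
        vr = VitalRateParams(
            survival_dd=GompertzParams(**data["survival_dd"]),
            survival_extreme=GompertzParams(**data["survival_extreme"]),
            maternity=CauchyParams(**data["maternity"]),
            stages=StageTable(**data["stages"]),
        )
        thr = ThermalThresholds(**data["thresholds"])
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"malformed profile {name_or_path!r}: {exc}") from exc
    return vr, thr
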