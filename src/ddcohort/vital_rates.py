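"""Age-specific vital rates over physiological time.

Survivorship L_x follows a two-parameter Gompertz survival function

    L(x) = exp(-b/a * (exp(a*u) - 1)),   u = x / age_scale

used in two variants: over degree-days within the developmental
thresholds (a = 5.3, b = 1.5, age_scale = 1000 DD) and over calendar
days at temperature extremes where no heat accumulates (a = -0.009,
b = 0.09501, age_scale = 1 day).  With a < 0 the extreme-condition curve
has a strictly positive horizontal asymptote exp(b/a): prolonged
exposure thins but never extinguishes a population.  The extreme curve
is exposed for analysis but deliberately not wired into the seasonal
simulator.

Gross maternity M_x (eggs per DD per female) is a truncated Cauchy
kernel anchored at the three observed landmarks of the oviposition
schedule: onset at 210 DD, a mode of 15 eggs/DD at 410 DD, cessation at
610 DD.  The kernel is zero outside [210, 610) and is not renormalised:
the peak height, not the integral, is the observed constraint.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import DegenerateCohortError, FitFailureError, InvalidInputError

__all__ = [
    "Stage",
    "StageTable",
    "GompertzParams",
    "CauchyParams",
    "VitalRateParams",
    "survival_dd",
    "conditional_survival",
    "survival_extreme",
    "maternity_dd",
    "stage_of",
    "fit_gompertz",
    "d_suzukii",
]


class Stage(str, enum.Enum):
    EGG = "egg"
    LARVA = "larva"
    PUPA = "pupa"
    ADULT = "adult"
    DEAD = "dead"


@dataclass(frozen=True)
class StageTable:
    """Degree-day boundaries partitioning age into life stages.

    Intervals are half-open [lo, hi): egg [0, 20.27), larva
    [20.27, 118), pupa [118, 199.9), adult [199.9, 610); ages at or
    beyond ``adult_end`` are dead.
    """

    egg_end: float = 20.27
    larva_end: float = 118.0
    pupa_end: float = 199.9
    adult_end: float = 610.0

    def __post_init__(self) -> None:
        if not 0.0 < self.egg_end < self.larva_end < self.pupa_end < self.adult_end:
            raise InvalidInputError("stage boundaries must be strictly increasing and positive")


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz survival parameters: shape ``a``, rate ``b``, and the
    age units per dimensionless x (``age_scale``)."""

    a: float
    b: float
    age_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.age_scale <= 0:
            raise InvalidInputError("age_scale must be positive")


@dataclass(frozen=True)
class CauchyParams:
    """Truncated Cauchy maternity kernel.

    ``location``/``scale`` are in DD on the physiological age axis;
    ``peak_rate`` is eggs per DD at the mode.  ``printed_location`` and
    ``printed_scale`` preserve the parameters as originally reported on
    an unstated normalised axis; they play no computational role.
    """

    location: float = 410.0
    scale: float = 50.0
    peak_rate: float = 15.0
    support_lo: float = 210.0
    support_hi: float = 610.0
    printed_location: float = 1.0
    printed_scale: float = 1.9

    def __post_init__(self) -> None:
        if not self.support_lo < self.location < self.support_hi:
            raise InvalidInputError("maternity mode must lie inside the support")
        if self.scale <= 0 or self.peak_rate < 0:
            raise InvalidInputError("scale must be positive and peak_rate non-negative")


def survival_dd(x, p: GompertzParams):
    """Proportion of a cohort surviving to physiological age ``x`` (DD).

    L(0) = 1 and L is non-increasing.  Accepts scalars or arrays.
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise InvalidInputError("age must be non-negative")
    u = xs / p.age_scale
    if p.a == 0.0:
        out = np.exp(-p.b * u)  # exponential limit of the Gompertz as a -> 0
    else:
        out = np.exp(-(p.b / p.a) * np.expm1(p.a * u))
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def conditional_survival(x: float, dx: float, p: GompertzParams) -> float:
    """Probability of surviving from age ``x`` to ``x + dx``: L(x+dx)/L(x)."""
    if x < 0 or dx < 0:
        raise InvalidInputError("age and increment must be non-negative")
    lx = survival_dd(x, p)
    if lx <= 0.0:
        raise DegenerateCohortError(f"survivorship already zero at age {x}")
    return min(1.0, survival_dd(x + dx, p) / lx)


def survival_extreme(t, p: GompertzParams):
    """Calendar-day survival under temperature extremes (no DD accrue).

    Same Gompertz form with age_scale 1 day; with the fitted a < 0 the
    curve levels off at exp(b/a) > 0 rather than reaching zero.
    """
    return survival_dd(t, p)


def maternity_dd(x, p: CauchyParams):
    """Gross maternity M_x: eggs per DD per female at physiological age ``x``.

    Zero below ``support_lo`` and at or above ``support_hi``; a Cauchy
    bump peaking at ``peak_rate`` on the support.  Accepts scalars or arrays.
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise InvalidInputError("age must be non-negative")
    kern = p.peak_rate / (1.0 + ((xs - p.location) / p.scale) ** 2)
    out = np.where((xs >= p.support_lo) & (xs < p.support_hi), kern, 0.0)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def stage_of(x: float, s: StageTable | None = None) -> Stage:
    """Life stage at DD age ``x`` (half-open interval lookup)."""
    s = s or StageTable()
    if x < 0:
        raise InvalidInputError("age must be non-negative")
    if x < s.egg_end:
        return Stage.EGG
    if x < s.larva_end:
        return Stage.LARVA
    if x < s.pupa_end:
        return Stage.PUPA
    if x < s.adult_end:
        return Stage.ADULT
    return Stage.DEAD


def fit_gompertz(
    ages,
    surviving_fraction,
    age_scale: float = 1.0,
    p0: tuple[float, float] = (1.0, 1.0),
) -> tuple[GompertzParams, float]:
    """Fit (a, b) of the Gompertz survival function by nonlinear least squares.

    Parameters
    ----------
    ages, surviving_fraction
        Observed life table: ages (in the same units ``age_scale`` maps
        from) and the fraction of the cohort alive at each age.
    age_scale
        Fixed calibration constant; not estimated.

    Returns
    -------
    (GompertzParams, chi2)
        The fitted parameters and a Pearson chi-square statistic,
        sum((obs - fit)^2 / fit), over the fitted points.

    Raises
    ------
    FitFailureError
        On non-convergence or degenerate input (no mortality signal,
        fewer than 3 points).
    """
    ages = np.asarray(ages, dtype=float)
    frac = np.asarray(surviving_fraction, dtype=float)
    if ages.size < 3:
        raise FitFailureError("need at least 3 points to fit a survival curve")
    if ages.size != frac.size:
        raise FitFailureError("ages and fractions differ in length")
    if np.any((frac < 0) | (frac > 1)):
        raise FitFailureError("surviving fractions must lie in [0, 1]")
    if np.ptp(ages) == 0:
        raise FitFailureError("all ages identical: degenerate design")
    if np.ptp(frac) == 0:
        raise FitFailureError("constant survival: no mortality signal to fit (b -> 0 boundary)")

    u = ages / age_scale

    def model(uu, a, b):
        with np.errstate(over="ignore"):
            if abs(a) < 1e-12:
                return np.exp(-b * uu)
            return np.exp(-(b / a) * np.expm1(a * uu))

    try:
        popt, _ = optimize.curve_fit(model, u, frac, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(f"Gompertz fit did not converge: {exc}") from exc
    a_hat, b_hat = float(popt[0]), float(popt[1])
    if abs(b_hat) < 1e-8:
        raise FitFailureError("rate parameter b collapsed to 0: no mortality signal in data")
    fitted = model(u, a_hat, b_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((frac - fitted) ** 2 / np.where(fitted > 0, fitted, np.nan)))
    return GompertzParams(a=a_hat, b=b_hat, age_scale=age_scale), chi2


@dataclass(frozen=True)
class VitalRateParams:
    """Bundle of all vital-rate parameters for one species profile."""

    survival_dd: GompertzParams = field(
        default_factory=lambda: GompertzParams(a=5.3, b=1.5, age_scale=1000.0)
    )
    survival_extreme: GompertzParams = field(
        default_factory=lambda: GompertzParams(a=-0.009, b=0.09501, age_scale=1.0)
    )
    maternity: CauchyParams = field(default_factory=CauchyParams)
    stages: StageTable = field(default_factory=StageTable)


def d_suzukii() -> VitalRateParams:
    """The default Drosophila suzukii vital-rate profile."""
    return VitalRateParams()
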