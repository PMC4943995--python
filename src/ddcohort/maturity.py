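"""Late-dormant reproductive potential: percent of dissected females
carrying mature eggs, regressed on degree-days accumulated from January 1.

The field observation behind this module: overwintered females become
reproductively mature as heat accumulates in late winter/spring, and the
percentage carrying mature eggs rises roughly linearly with DD from
January 1.  A simple ordinary-least-squares line on the percent scale
(0-100) captures this; predictions are clipped to [0, 100] for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import FitFailureError, InvalidInputError

__all__ = ["DissectionRecord", "MaturityRegression", "fit_maturity", "predict_maturity"]


@dataclass(frozen=True)
class DissectionRecord:
    """One dissection survey: region label, DD midpoint of the collection
    period (single sine, from Jan 1), and mature-egg counts."""

    region: str
    dd_midpoint: float
    n_dissected: int
    n_mature: int

    def __post_init__(self) -> None:
        if self.dd_midpoint < 0:
            raise InvalidInputError("dd_midpoint must be non-negative")
        if not 0 <= self.n_mature <= self.n_dissected:
            raise InvalidInputError("need 0 <= n_mature <= n_dissected")
        if self.n_dissected <= 0:
            raise InvalidInputError("n_dissected must be positive")

    @property
    def percent_mature(self) -> float:
        return 100.0 * self.n_mature / self.n_dissected


@dataclass(frozen=True)
class MaturityRegression:
    """Fitted line: percent mature = slope * DD + intercept."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int


def fit_maturity(records: list[DissectionRecord]) -> MaturityRegression:
    """OLS of percent-mature on DD from January 1.

    Requires at least 3 records with non-degenerate DD spread.
    """
    if len(records) < 3:
        raise FitFailureError("need at least 3 dissection records")
    x = np.array([r.dd_midpoint for r in records], dtype=float)
    y = np.array([r.percent_mature for r in records], dtype=float)
    if np.ptp(x) == 0:
        raise FitFailureError("all DD midpoints identical: cannot fit a slope")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    fvalue = float(model.fvalue) if np.isfinite(model.fvalue) else float("inf")
    return MaturityRegression(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=fvalue,
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
    )


def predict_maturity(dd, model: MaturityRegression):
    """Predicted percent of females with mature eggs at ``dd`` DD from
    January 1, clipped to [0, 100].  Accepts scalars or arrays."""
    dds = np.asarray(dd, dtype=float)
    if np.any(dds < 0):
        raise InvalidInputError("DD must be non-negative")
    out = np.clip(model.slope * dds + model.intercept, 0.0, 100.0)
    return float(out) if np.isscalar(dd) or out.ndim == 0 else out
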