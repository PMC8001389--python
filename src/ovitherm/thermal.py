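"""Linear temperature-dependent development-rate model.

Within the suboptimal temperature range the development rate (1/days) of an
egg is close to linear in temperature, r(T) = a + b·T. Two biologically
meaningful quantities follow from the fitted line: the lower development
threshold T0 = −a/b, the temperature at which the rate extrapolates to
zero, and the thermal constant K = 1/b, the number of degree-days above T0
needed to complete development. Rates are the reciprocals of per-condition
mean durations, fitted by ordinary least squares within each RH regime, by
default excluding supraoptimal temperatures where the rate has already
turned over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .errors import FitError, ParameterError

__all__ = [
    "RatePoint",
    "RateRegression",
    "development_rates",
    "fit_linear_rate_model",
    "fit_rate_models",
    "regression_from_coefficients",
    "predict_duration",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatePoint:
    """Mean development rate (1/days) at one temperature × RH condition."""

    temperature_c: float
    rate: float
    rh_regime: str
    n: int

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError(
                f"rate must be positive, got {self.rate} at {self.temperature_c} °C"
            )


@dataclass(frozen=True)
class RateRegression:
    """Fitted line r = a + b·T for one RH regime with derived T0 and K.

    ``T0 = -a/b`` (°C) and ``K = 1/b`` (degree-days) hold exactly; fit
    statistics are NaN when the regression was built directly from given
    coefficients rather than fitted to points.
    """

    rh_regime: str
    slope_b: float
    intercept_a: float
    F: float
    p: float
    R2: float
    T0: float
    K: float
    temperatures_used: tuple[float, ...]

    @property
    def valid(self) -> bool:
        return self.slope_b > 0


def regression_from_coefficients(
    slope_b: float,
    intercept_a: float,
    rh_regime: str = "",
    temperatures_used: Sequence[float] = (),
) -> RateRegression:
    """Build a :class:`RateRegression` from known line coefficients.

    Used to derive T0 and K from published regression tables; the defining
    identities T0 = −a/b, K = 1/b are applied exactly.
    """
    if slope_b <= 0:
        raise FitError(f"slope must be positive to derive T0 and K, got {slope_b}")
    return RateRegression(
        rh_regime=rh_regime,
        slope_b=slope_b,
        intercept_a=intercept_a,
        F=float("nan"),
        p=float("nan"),
        R2=float("nan"),
        T0=-intercept_a / slope_b,
        K=1.0 / slope_b,
        temperatures_used=tuple(temperatures_used),
    )


def development_rates(summaries: pd.DataFrame) -> list[RatePoint]:
    """Reciprocal of each per-condition mean duration, as rate points.

    ``summaries`` is the frame from
    :func:`ovitherm.devtime.summarize_development`. Conditions with a
    missing or non-positive mean are skipped with a warning.
    """
    points = []
    for row in summaries.itertuples(index=False):
        mean = row.mean_days
        if mean is None or not mean > 0:
            logger.warning(
                "skipping condition %s °C / %s: no usable mean duration",
                row.temperature_c,
                row.rh_regime,
            )
            continue
        points.append(
            RatePoint(
                temperature_c=float(row.temperature_c),
                rate=1.0 / float(mean),
                rh_regime=str(row.rh_regime),
                n=int(row.n),
            )
        )
    return points


def fit_linear_rate_model(
    points: Sequence[RatePoint], exclude_supraoptimal: bool = True
) -> RateRegression:
    """Unweighted OLS of rate on temperature for one RH regime.

    With ``exclude_supraoptimal`` (the default) every point warmer than the
    temperature of the empirical rate maximum is dropped before fitting,
    restricting the line to the range where it is a sensible description.
    A fit with non-positive slope is returned flagged invalid (T0/K NaN).
    """
    if not points:
        raise FitError("no rate points supplied")
    regimes = {p.rh_regime for p in points}
    if len(regimes) != 1:
        raise FitError(f"rate points span multiple RH regimes: {sorted(regimes)}")
    regime = regimes.pop()

    pts = sorted(points, key=lambda p: p.temperature_c)
    if exclude_supraoptimal:
        t_opt = max(pts, key=lambda p: p.rate).temperature_c
        pts = [p for p in pts if p.temperature_c <= t_opt]
    if len(pts) < 3:
        raise FitError(f"need >= 3 rate points to fit, have {len(pts)}")

    x = [p.temperature_c for p in pts]
    y = [p.rate for p in pts]
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2)
    n = len(pts)
    if fit.stderr and fit.stderr > 0:
        f_stat = (slope / float(fit.stderr)) ** 2
    else:
        f_stat = float("inf")
    if slope <= 0:
        logger.warning("non-positive slope %.4g for regime %s: invalid fit", slope, regime)
        t0 = k = float("nan")
    else:
        t0 = -intercept / slope
        k = 1.0 / slope
    return RateRegression(
        rh_regime=regime,
        slope_b=slope,
        intercept_a=intercept,
        F=f_stat,
        p=float(fit.pvalue),
        R2=r2,
        T0=t0,
        K=k,
        temperatures_used=tuple(x),
    )


def fit_rate_models(
    points: Sequence[RatePoint], exclude_supraoptimal: bool = True
) -> dict[str, RateRegression]:
    """Fit the linear rate model separately within each RH regime."""
    by_regime: dict[str, list[RatePoint]] = {}
    for p in points:
        by_regime.setdefault(p.rh_regime, []).append(p)
    return {
        regime: fit_linear_rate_model(pts, exclude_supraoptimal)
        for regime, pts in sorted(by_regime.items())
    }


def predict_duration(reg: RateRegression, temperature_c: float) -> float:
    """Expected development duration K/(T − T0) in days at ``temperature_c``."""
    if not reg.valid or reg.T0 != reg.T0:
        raise FitError("regression is not a valid development-rate fit")
    if temperature_c <= reg.T0:
        raise ParameterError(
            f"no development at {temperature_c} °C: at or below the lower "
            f"threshold {reg.T0:.4g} °C"
        )
    return reg.K / (temperature_c - reg.T0)
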