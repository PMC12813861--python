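"""Quadratic temperature-demand models.

Daily ambulance demand in a stratum follows a U-shaped (convex
quadratic) relationship with daily mean temperature: demand is lowest
at moderate temperatures and rises toward both cold and hot extremes.
The model per stratum is ordinary least squares of the daily count on
(1, T, T^2).  Projection to a target year multiplies a fitted equation
by that stratum's population-change weight; the population-wide curve
is the coefficientwise sum of the (possibly weighted) stratum curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "QuadraticEquation",
    "TemperatureDemandModel",
    "TemperatureDemandResults",
    "read_temperature",
    "fit_quadratic",
    "project_equation",
    "combine",
    "vertex",
    "curve_table",
]

TEMP_PLAUSIBLE = (-20.0, 50.0)


def read_temperature(path: str | Path) -> pd.Series:
    """Read a ``date,temperature`` daily series (°C).

    Duplicated dates or values outside a plausible -20..50 °C range are
    rejected.
    """
    df = pd.read_csv(path, comment="#")
    if missing := {"date", "temperature"} - set(df.columns):
        raise ValueError(f"temperature file {path} lacks columns: {sorted(missing)}")
    dates = pd.to_datetime(df["date"])
    if dates.duplicated().any():
        raise ValueError(f"duplicate dates in temperature series {path}")
    temps = df["temperature"].astype(float)
    lo, hi = TEMP_PLAUSIBLE
    bad = (temps < lo) | (temps > hi)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} temperatures outside plausible range {lo}..{hi} °C in {path}"
        )
    return pd.Series(temps.to_numpy(), index=pd.DatetimeIndex(dates), name="temperature").sort_index()


@dataclass(frozen=True)
class QuadraticEquation:
    """Demand = constant + b1*T + b2*T^2 (counts/day, T in °C).

    ``ci_b1``/``ci_b2`` are 95% confidence intervals where the equation
    came from a fit; combined (summed) equations carry no intervals.
    """

    constant: float
    b1: float
    b2: float
    ci_b1: tuple[float, float] | None = None
    ci_b2: tuple[float, float] | None = None
    adj_r2: float | None = None
    nobs: int | None = None
    label: str | None = None

    def predict(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = self.constant + self.b1 * t + self.b2 * t**2
        return out if out.ndim else float(out)

    __call__ = predict

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.constant, self.b1, self.b2)

    def scaled(self, weight: float, label: str | None = None) -> "QuadraticEquation":
        return project_equation(self, weight, label=label)

    def vertex(self) -> float:
        return vertex(self)

    def format(self, ndigits: int = 2) -> str:
        c, b1, b2 = (round(v, ndigits) for v in self.coefficients)
        sign1, sign2 = ("-" if b1 < 0 else "+"), ("-" if b2 < 0 else "+")
        return f"{c:.{ndigits}f} {sign1} {abs(b1):.{ndigits}f}T {sign2} {abs(b2):.{ndigits}f}T^2"


class TemperatureDemandModel:
    """OLS model of a stratum's daily demand on daily mean temperature.

    Parameters
    ----------
    counts : pandas Series of daily event counts indexed by date
        (zero-demand days included).
    temperature : pandas Series of daily mean temperature (°C) indexed
        by date.  Only dates present in both series are used.
    label : optional stratum name carried through to the results.
    """

    def __init__(self, counts: pd.Series, temperature: pd.Series, label: str | None = None):
        df = pd.concat({"y": counts, "t": temperature}, axis=1, join="inner").dropna()
        if df["t"].nunique() < 3:
            raise ValueError(
                "need at least 3 distinct temperature values to fit a quadratic "
                f"(got {df['t'].nunique()})"
            )
        self.endog = df["y"].to_numpy(dtype=float)
        self.temperature = df["t"].to_numpy(dtype=float)
        self.dates = df.index
        self.label = label
        self.exog = sm.add_constant(
            np.column_stack([self.temperature, self.temperature**2])
        )

    @classmethod
    def from_demand_table(cls, daily, band, sex, temperature: pd.Series) -> "TemperatureDemandModel":
        counts = daily.stratum_series(band, sex)
        label = f"{band if isinstance(band, str) else band.label}/{sex}"
        return cls(counts, temperature, label=label)

    def fit(self) -> "TemperatureDemandResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return TemperatureDemandResults(self, res)


class TemperatureDemandResults:
    """Fit results: coefficients, t-based 95% CIs, adjusted R^2."""

    def __init__(self, model: TemperatureDemandModel, sm_results):
        self.model = model
        self._res = sm_results

    @property
    def params(self) -> np.ndarray:
        return self._res.params

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def adj_r2(self) -> float:
        # constant response => zero total variance; report 0 rather than nan
        with np.errstate(divide="ignore", invalid="ignore"):
            v = self._res.rsquared_adj
        return float(v) if np.isfinite(v) else 0.0

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return self._res.conf_int(alpha)

    @property
    def equation(self) -> QuadraticEquation:
        ci = self.conf_int()
        c, b1, b2 = self.params
        return QuadraticEquation(
            constant=float(c),
            b1=float(b1),
            b2=float(b2),
            ci_b1=(float(ci[1, 0]), float(ci[1, 1])),
            ci_b2=(float(ci[2, 0]), float(ci[2, 1])),
            adj_r2=self.adj_r2,
            nobs=self.nobs,
            label=self.model.label,
        )

    def predict(self, t) -> np.ndarray | float:
        return self.equation.predict(t)

    def summary(self):
        return self._res.summary(
            xname=["constant", "T", "T^2"],
            yname="daily demand",
            title=f"Temperature-demand quadratic ({self.model.label or 'stratum'})",
        )


def fit_quadratic(counts: pd.Series, temperature: pd.Series, label: str | None = None) -> QuadraticEquation:
    """Convenience wrapper: fit and return the equation only."""
    return TemperatureDemandModel(counts, temperature, label=label).fit().equation


def project_equation(
    m: QuadraticEquation, weight: float, label: str | None = None
) -> QuadraticEquation:
    """Scale an equation by a population-change weight.

    All three coefficients (and the CI bounds) are multiplied by the
    weight; the goodness of fit of the base-year equation is unchanged
    by rescaling, so adj_r2 carries over.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    scale = lambda ci: (ci[0] * weight, ci[1] * weight) if ci is not None else None
    return QuadraticEquation(
        constant=m.constant * weight,
        b1=m.b1 * weight,
        b2=m.b2 * weight,
        ci_b1=scale(m.ci_b1),
        ci_b2=scale(m.ci_b2),
        adj_r2=m.adj_r2,
        nobs=m.nobs,
        label=label if label is not None else m.label,
    )


def combine(models: Iterable[QuadraticEquation], label: str | None = None) -> QuadraticEquation:
    """Coefficientwise sum of stratum equations (the population-wide curve).

    The sum of per-stratum fits carries no single-fit CIs or adj R^2.
    """
    models = list(models)
    if not models:
        raise ValueError("cannot combine an empty list of equations")
    if len(models) == 1:
        return models[0]
    return QuadraticEquation(
        constant=sum(m.constant for m in models),
        b1=sum(m.b1 for m in models),
        b2=sum(m.b2 for m in models),
        label=label,
    )


def vertex(m: QuadraticEquation) -> float:
    """Temperature of minimum demand, -b1/(2 b2); requires convexity."""
    if m.b2 <= 0:
        raise ValueError(f"no interior minimum: quadratic coefficient {m.b2} <= 0")
    return -m.b1 / (2.0 * m.b2)


def curve_table(
    m: QuadraticEquation, t_min: float, t_max: float, step: float
) -> pd.DataFrame:
    """Tabulate the curve on a temperature grid.

    Predicted demand is reported raw; negative values (possible under
    extreme extrapolation) are flagged, never clamped.
    """
    if not t_min < t_max:
        raise ValueError(f"need t_min < t_max, got {t_min} >= {t_max}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    grid = np.arange(t_min, t_max + step / 2, step)
    pred = m.predict(grid)
    return pd.DataFrame(
        {"T": grid, "predicted": pred, "negative": pred < 0}
    )
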