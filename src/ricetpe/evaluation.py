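"""Measured-vs-simulated agreement statistics for model certification.

Given paired series of measured (X) and simulated (Y) values — biomass or
yield at matched sampling dates — the report computes ordinary least-squares
slope/intercept/R^2 of Y on X, the Welch (unequal-variance) two-sample
t-test p-value, the normalised root-mean-square error

    RMSEn = sqrt(mean((Y - X)^2)) / mean(X) * 100   [%]

and the Willmott-style index of modelling agreement

    Meff = 1 - sum((Y - X)^2) / sum((|Y - Xbar| + |X - Xbar|)^2).

A prediction is considered certified when slope and R^2 and Meff are close
to 1, the intercept close to 0, p > 0.05, and RMSEn comparable to the CV of
the field measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "FitStats",
    "rmse_n",
    "m_eff",
    "regression_stats",
    "welch_t",
    "cv_band_coverage",
    "fit_stats",
    "evaluation_report",
    "CALIBRATION_TOLERANCES",
]

#: Desired relative calibration tolerance per variable class: fraction of
#: the measured value within which simulated values should fall.
CALIBRATION_TOLERANCES = {
    "storage_organ_biomass": 0.05,
    "green_leaf_biomass": 0.10,
    "AGB": 0.10,
    "LAI": 0.15,
    "dead_leaf_biomass": 0.15,
}


@dataclass(frozen=True)
class PairedSeries:
    """Measured (x) / simulated (y) value pairs for one variable."""

    x: np.ndarray
    y: np.ndarray
    variable: str = "GY"
    dataset: str = "validation"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be one-dimensional and equal length")
        if x.size < 2:
            raise ValueError("at least two pairs are required")


@dataclass(frozen=True)
class FitStats:
    variable: str
    dataset: str
    n: int
    slope: float
    intercept: float
    r2: float
    p_welch: float
    rmse_n: float  # percent
    m_eff: float


def rmse_n(series: PairedSeries) -> float:
    """Normalised RMSE in percent of the mean measured value."""
    x, y = series.x, series.y
    if x.sum() <= 0:
        raise ValueError("sum of measured values must be > 0")
    return float(np.sqrt(np.mean((y - x) ** 2)) / x.mean() * 100.0)


def m_eff(series: PairedSeries) -> float:
    """Index of modelling agreement; 1 = perfect, <= 1 always."""
    x, y = series.x, series.y
    xbar = x.mean()
    denom = np.sum((np.abs(y - xbar) + np.abs(x - xbar)) ** 2)
    if denom <= 0:
        raise ValueError("degenerate series: X constant and Y equal to its mean")
    return float(1.0 - np.sum((y - x) ** 2) / denom)


def regression_stats(series: PairedSeries) -> tuple[float, float, float]:
    """(slope, intercept, R^2) of the OLS regression of simulated on measured."""
    x, y = series.x, series.y
    if x.std() == 0:
        raise ValueError("measured values are constant; regression undefined")
    if y.std() == 0:
        # degenerate but well-defined: flat fit explains no variance
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def welch_t(series: PairedSeries) -> float:
    """p-value of the unequal-variance two-sample t-test between X and Y."""
    x, y = series.x, series.y
    if x.std() == 0 and y.std() == 0:
        if np.isclose(x.mean(), y.mean()):
            return 1.0
        raise ValueError("both samples degenerate with different means")
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def cv_band_coverage(series: PairedSeries, cv: float) -> float:
    """Fraction of pairs with |Y - X| within cv * X of the measurement."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    x, y = series.x, series.y
    return float(np.mean(np.abs(y - x) <= cv * x))


def fit_stats(series: PairedSeries) -> FitStats:
    slope, intercept, r2 = regression_stats(series)
    return FitStats(
        variable=series.variable,
        dataset=series.dataset,
        n=series.x.size,
        slope=slope,
        intercept=intercept,
        r2=r2,
        p_welch=welch_t(series),
        rmse_n=rmse_n(series),
        m_eff=m_eff(series),
    )


def evaluation_report(groups: list[PairedSeries]) -> pd.DataFrame:
    """One row of agreement statistics per (dataset, variable) series."""
    rows = []
    for s in groups:
        if s.x.size == 0:
            continue
        f = fit_stats(s)
        rows.append(
            {
                "dataset": f.dataset,
                "variable": f.variable,
                "n": f.n,
                "slope": f.slope,
                "intercept": f.intercept,
                "r2": f.r2,
                "p_welch": f.p_welch,
                "rmse_n_pct": f.rmse_n,
                "m_eff": f.m_eff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dataset", "variable", "n", "slope", "intercept", "r2", "p_welch", "rmse_n_pct", "m_eff"],
    )
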