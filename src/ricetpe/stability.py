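"""Per-variety yield stability and adaptability indicators.

For one variety, the best-rainfed-season irrigated and rainfed yields across
years j = 1..m and environments k = 1..q form matrices YP and YA.  Five
scalars summarise them:

* gamma — mean rainfed yield (t/ha), productivity;
* delta — RMS deviation of rainfed from irrigated yield over the mean
  irrigated yield, the normalised drought yield penalty;
* lambda — population coefficient of variation of YA, overall stability;
* phi — CV of the environment means of YA, spatial variability;
* psi — CV of the year means of YA, temporal variability.

All five are root-mean-square forms, so lambda is literally the CV of YA
and, by the law of total variance, lambda >= phi and lambda >= psi.  Lower
delta/lambda/phi/psi and higher gamma mark a better variety.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import SeasonSlice

__all__ = [
    "StabilityIndicators",
    "BestSeasonYields",
    "gamma",
    "delta",
    "lambda_",
    "phi",
    "psi",
    "compute_indicators",
    "indicators_for_scope",
    "best_season_yields",
    "indicator_table",
]


@dataclass(frozen=True)
class StabilityIndicators:
    variety: str
    scope: str  # "ALL" or a TPE class / pooled severity / timing scope
    gamma: float
    delta: float
    lambda_: float
    phi: float
    psi: float
    n_environments: int
    n_years: int


@dataclass
class BestSeasonYields:
    """Year x environment matrices of one variety's best-season yields."""

    variety: str
    env_ids: list[str]
    yp: np.ndarray  # (m years, q environments), irrigated
    ya: np.ndarray  # (m years, q environments), rainfed

    def __post_init__(self) -> None:
        if self.yp.shape != self.ya.shape:
            raise ValueError("YP and YA must share shape (years, environments)")
        if self.yp.shape[1] != len(self.env_ids):
            raise ValueError("environment axis does not match env_ids")


def _check(ya: np.ndarray) -> np.ndarray:
    ya = np.asarray(ya, dtype=float)
    if ya.size == 0:
        raise ValueError("empty yield matrix")
    return ya


def gamma(ya: np.ndarray) -> float:
    """Mean rainfed yield over all years and environments."""
    return float(_check(ya).mean())


def delta(yp: np.ndarray, ya: np.ndarray) -> float:
    """RMS(yp - ya) / mean(yp): normalised distance of rainfed from irrigated."""
    yp = np.asarray(yp, dtype=float)
    ya = _check(ya)
    if yp.shape != ya.shape:
        raise ValueError("YP and YA must be aligned")
    mean_p = yp.mean()
    if mean_p <= 0:
        raise ValueError("mean irrigated yield must be > 0")
    return float(np.sqrt(np.mean((yp - ya) ** 2)) / mean_p)


def lambda_(ya: np.ndarray) -> float:
    """Population CV of YA over all cells (overall stability)."""
    ya = _check(ya)
    g = ya.mean()
    if g <= 0:
        raise ValueError("gamma must be > 0")
    return float(np.sqrt(np.mean((ya - g) ** 2)) / g)


def phi(ya: np.ndarray) -> float:
    """CV of the per-environment (column) means: spatial variability."""
    ya = _check(ya)
    g = ya.mean()
    if g <= 0:
        raise ValueError("gamma must be > 0")
    env_means = ya.mean(axis=0)
    return float(np.sqrt(np.mean((env_means - g) ** 2)) / g)


def psi(ya: np.ndarray) -> float:
    """CV of the per-year (row) means: temporal variability."""
    ya = _check(ya)
    g = ya.mean()
    if g <= 0:
        raise ValueError("gamma must be > 0")
    year_means = ya.mean(axis=1)
    return float(np.sqrt(np.mean((year_means - g) ** 2)) / g)


def compute_indicators(yields: BestSeasonYields, scope: str = "ALL") -> StabilityIndicators:
    """All five indicators for one variety over one environment set."""
    m, q = yields.ya.shape
    return StabilityIndicators(
        variety=yields.variety,
        scope=scope,
        gamma=gamma(yields.ya),
        delta=delta(yields.yp, yields.ya),
        lambda_=lambda_(yields.ya),
        phi=phi(yields.ya),
        psi=psi(yields.ya),
        n_environments=q,
        n_years=m,
    )


def indicators_for_scope(
    yields: BestSeasonYields,
    env_labels: dict[str, str],
    scope: str = "ALL",
) -> StabilityIndicators:
    """Restrict the environment columns to a scope, then compute.

    ``scope`` is "ALL", a TPE class ("M2"), a pooled severity letter
    ("S"/"M"/"L") or a pooled timing digit ("1"/"2"/"3").
    """
    if scope == "ALL":
        keep = list(range(len(yields.env_ids)))
    else:
        def in_scope(label: str) -> bool:
            if scope in ("L", "M", "S"):
                return label[0] == scope
            if scope in ("1", "2", "3"):
                return label[1] == scope
            return label == scope

        keep = [k for k, e in enumerate(yields.env_ids) if in_scope(env_labels[e])]
    if not keep:
        raise ValueError(f"scope {scope!r} contains no environments")
    sub = BestSeasonYields(
        variety=yields.variety,
        env_ids=[yields.env_ids[k] for k in keep],
        yp=yields.yp[:, keep],
        ya=yields.ya[:, keep],
    )
    return compute_indicators(sub, scope)


def best_season_yields(slices: dict[str, SeasonSlice], variety: str) -> BestSeasonYields:
    """Assemble one variety's YP/YA matrices from per-environment slices."""
    env_ids = list(slices)
    if not env_ids:
        raise ValueError("no environments supplied")
    cols_p, cols_a = [], []
    for env_id in env_ids:
        s = slices[env_id]
        if variety not in s.varieties:
            raise KeyError(f"variety {variety!r} absent in environment {env_id}")
        v = s.varieties.index(variety)
        cols_p.append(s.py_jv[:, v])
        cols_a.append(s.ay_jv[:, v])
    return BestSeasonYields(
        variety=variety,
        env_ids=env_ids,
        yp=np.column_stack(cols_p),
        ya=np.column_stack(cols_a),
    )


def indicator_table(
    slices: dict[str, SeasonSlice],
    env_labels: dict[str, str],
    scopes: list[str],
    varieties: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of the five indicators per (variety, scope).

    Scopes with no environments are skipped silently, so callers may pass
    the full scope list even when some TPE classes are absent from a grid.
    """
    if varieties is None:
        varieties = list(next(iter(slices.values())).varieties)
    rows = []
    for name in varieties:
        yields = best_season_yields(slices, name)
        for scope in scopes:
            try:
                ind = indicators_for_scope(yields, env_labels, scope)
            except ValueError:
                continue
            rows.append(
                {
                    "variety": name,
                    "scope": scope,
                    "gamma": ind.gamma,
                    "delta": ind.delta,
                    "lambda": ind.lambda_,
                    "phi": ind.phi,
                    "psi": ind.psi,
                    "n_environments": ind.n_environments,
                    "n_years": ind.n_years,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["variety", "scope", "gamma", "delta", "lambda", "phi", "psi", "n_environments", "n_years"],
    )
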