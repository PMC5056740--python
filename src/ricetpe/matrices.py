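"""P/A matrix organisation, cleaning and best-rainfed-season selection.

From each environment's simulated cube, four panels are organised per
variety — irrigated grain yield PY, rainfed grain yield AY, and the rainfed
stage drought indices AV (vegetative) and AR (reproductive) — each a sowing
date x year matrix.  Stacking the variety axis gives the combined panels
PY', AY', AV', AR' from which the best rainfed season is selected.

Cleaning removes every sowing-date row in which *any* irrigated yield is
zero (the sowing date is not suitable for rice growth anywhere in the
record); zero rainfed yields are legitimate drought outcomes and are kept.

The best rainfed season is the sowing date with the smallest yield
coefficient of variation among the three highest mean rainfed yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import GEICube

__all__ = [
    "CombinedPanels",
    "BestSeason",
    "SeasonSlice",
    "NoSuitableSeasonError",
    "panels_from_cube",
    "clean_unsuitable_dates",
    "mean_rainfed_yield_by_date",
    "cv_by_date",
    "select_best_season",
    "best_season_slice",
]


class NoSuitableSeasonError(ValueError):
    """Raised when cleaning removes every sowing date of an environment."""


@dataclass
class CombinedPanels:
    """The four variety-stacked panels of one environment.

    Arrays are indexed ``[variety v, sowing date i, year j]`` and share one
    index set; ``sowing_index`` holds the original 1-based sowing-date
    indices that survived cleaning.
    """

    env_id: str
    varieties: list[str]
    sowing_index: np.ndarray  # original 1-based sowing-date index
    sowing_doys: np.ndarray
    years: np.ndarray
    py: np.ndarray
    ay: np.ndarray
    av: np.ndarray
    ar: np.ndarray

    @property
    def n_dates(self) -> int:
        return len(self.sowing_index)


@dataclass(frozen=True)
class BestSeason:
    env_id: str
    sowing_index: int  # 1-based index of the selected sowing date
    sowing_doy: int
    ry: float  # mean rainfed yield over years x varieties, t/ha
    cv: float  # coefficient of variation of those yields


@dataclass
class SeasonSlice:
    """Year x variety arrays at one environment's best rainfed season."""

    env_id: str
    varieties: list[str]
    years: np.ndarray
    py_jv: np.ndarray
    ay_jv: np.ndarray
    av_jv: np.ndarray
    ar_jv: np.ndarray


def panels_from_cube(cube: GEICube) -> CombinedPanels:
    """Organise a simulated cube into the four combined panels (uncleaned)."""
    return CombinedPanels(
        env_id=cube.env_id,
        varieties=list(cube.varieties),
        sowing_index=np.arange(1, len(cube.sowing_doys) + 1),
        sowing_doys=cube.sowing_doys.copy(),
        years=cube.years.copy(),
        py=cube.p.copy(),
        ay=cube.a.copy(),
        av=cube.div.copy(),
        ar=cube.dir.copy(),
    )


def clean_unsuitable_dates(panels: CombinedPanels) -> CombinedPanels:
    """Drop sowing-date rows whose irrigated yield is zero anywhere.

    A zero in PY for sowing date i — any year, any variety — marks the date
    as unsuitable; the row is removed from all four panels so they stay
    index-aligned.  Raises :class:`NoSuitableSeasonError` if nothing
    survives.
    """
    keep = ~np.any(panels.py == 0.0, axis=(0, 2))
    if not np.any(keep):
        raise NoSuitableSeasonError(
            f"environment {panels.env_id}: every sowing date has a zero irrigated yield"
        )
    return CombinedPanels(
        env_id=panels.env_id,
        varieties=list(panels.varieties),
        sowing_index=panels.sowing_index[keep],
        sowing_doys=panels.sowing_doys[keep],
        years=panels.years.copy(),
        py=panels.py[:, keep, :],
        ay=panels.ay[:, keep, :],
        av=panels.av[:, keep, :],
        ar=panels.ar[:, keep, :],
    )


def mean_rainfed_yield_by_date(panels: CombinedPanels) -> np.ndarray:
    """RY_i: mean rainfed yield over years and varieties, per sowing date."""
    return panels.ay.mean(axis=(0, 2))


def cv_by_date(panels: CombinedPanels) -> np.ndarray:
    """CV_i: population std of rainfed yield over years x varieties / RY_i."""
    ry = mean_rainfed_yield_by_date(panels)
    if np.any(ry <= 0):
        raise ValueError(
            f"environment {panels.env_id}: RY is zero for some sowing date; CV undefined"
        )
    sd = panels.ay.std(axis=(0, 2))  # population (1/N) normalisation
    return sd / ry


def select_best_season(panels: CombinedPanels) -> BestSeason:
    """Smallest CV among the three sowing dates with highest RY.

    Ties in RY are broken toward the earlier sowing date when choosing the
    top three, and CV ties likewise resolve to the earlier date, so the
    selection is deterministic.
    """
    ry = mean_rainfed_yield_by_date(panels)
    cv = cv_by_date(panels)
    k = min(3, len(ry))
    # stable sort on -RY keeps earlier dates first among equals
    top = np.argsort(-ry, kind="stable")[:k]
    best = top[np.lexsort((panels.sowing_index[top], cv[top]))[0]]
    return BestSeason(
        env_id=panels.env_id,
        sowing_index=int(panels.sowing_index[best]),
        sowing_doy=int(panels.sowing_doys[best]),
        ry=float(ry[best]),
        cv=float(cv[best]),
    )


def best_season_slice(panels: CombinedPanels, best: BestSeason) -> SeasonSlice:
    """Extract the year x variety arrays at the selected best season."""
    pos = np.flatnonzero(panels.sowing_index == best.sowing_index)
    if pos.size != 1:
        raise ValueError(
            f"sowing index {best.sowing_index} not present in cleaned panels of {panels.env_id}"
        )
    i = int(pos[0])
    return SeasonSlice(
        env_id=panels.env_id,
        varieties=list(panels.varieties),
        years=panels.years.copy(),
        py_jv=panels.py[:, i, :].T.copy(),  # -> (year j, variety v)
        ay_jv=panels.ay[:, i, :].T.copy(),
        av_jv=panels.av[:, i, :].T.copy(),
        ar_jv=panels.ar[:, i, :].T.copy(),
    )
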