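"""CSV / GeoJSON schemas for every pipeline stage.

All tables are UTF-8 CSV with a header row and strictly validated column
names; geographic outputs are WGS84 point features (15 arc-minute cell
centres) written as plain GeoJSON.  Writing then reading any table
reproduces values to full float precision (%.17g serialisation, round-trip
parsing).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import BestSeason
from .synthetic import EnvironmentParams, GEICube

__all__ = [
    "SchemaError",
    "write_gei_long",
    "read_gei_long",
    "write_environments_csv",
    "read_environments_csv",
    "write_environments_geojson",
    "write_best_seasons",
    "read_best_seasons",
    "write_classification",
    "read_classification",
    "classification_geojson",
    "write_indicators",
    "read_indicators",
    "write_ranks",
    "write_paired_series",
    "read_paired_series",
]

GEI_COLUMNS = ["env_id", "variety", "regime", "sowing_index", "year", "yield", "div", "dir"]
BEST_SEASON_COLUMNS = ["env_id", "sowing_index", "sowing_doy", "ry", "cv"]
CLASSIFICATION_COLUMNS = ["env_id", "lon", "lat", "label", "f75", "av_bar", "ar_bar"]
INDICATOR_COLUMNS = ["variety", "scope", "gamma", "delta", "lambda", "phi", "psi", "n_environments", "n_years"]
PAIRED_COLUMNS = ["dataset", "variable", "x", "y"]


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


def _require_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(f"{what}: missing columns {missing}, unexpected columns {extra}")


def _write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips every IEEE double exactly
    df.to_csv(path, index=False, float_format="%.17g")


# -- GEI long format ---------------------------------------------------------


def write_gei_long(cubes: dict[str, GEICube], path) -> None:
    """Serialise simulated cubes to the long-format run table.

    Irrigated rows carry drought indices of 1 (no water limitation);
    rainfed rows carry the simulated stage indices.
    """
    frames = []
    for cube in cubes.values():
        nv, ni, nj = cube.p.shape
        v_idx, i_idx, j_idx = np.meshgrid(np.arange(nv), np.arange(ni), np.arange(nj), indexing="ij")
        base = {
            "env_id": cube.env_id,
            "variety": np.array(cube.varieties)[v_idx.ravel()],
            "sowing_index": i_idx.ravel() + 1,
            "year": cube.years[j_idx.ravel()],
        }
        irr = pd.DataFrame({**base, "regime": "irrigated", "yield": cube.p.ravel(), "div": 1.0, "dir": 1.0})
        rf = pd.DataFrame(
            {**base, "regime": "rainfed", "yield": cube.a.ravel(), "div": cube.div.ravel(), "dir": cube.dir.ravel()}
        )
        frames.append(irr)
        frames.append(rf)
    df = pd.concat(frames, ignore_index=True)[GEI_COLUMNS]
    _write_csv(df, path)


def read_gei_long(path, sowing_doys: np.ndarray | None = None) -> dict[str, GEICube]:
    """Rebuild per-environment cubes from the long-format run table."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, GEI_COLUMNS, "GEI long table")
    cubes: dict[str, GEICube] = {}
    for env_id, g in df.groupby("env_id", sort=False):
        varieties = list(pd.unique(g["variety"]))
        sowing = np.sort(pd.unique(g["sowing_index"]))
        years = np.sort(pd.unique(g["year"]))
        shape = (len(varieties), len(sowing), len(years))
        v_pos = {n: k for k, n in enumerate(varieties)}
        i_pos = {n: k for k, n in enumerate(sowing)}
        j_pos = {n: k for k, n in enumerate(years)}
        arrays = {name: np.full(shape, np.nan) for name in ("p", "a", "div", "dir")}
        for regime, sub in g.groupby("regime"):
            vi = sub["variety"].map(v_pos).to_numpy()
            ii = sub["sowing_index"].map(i_pos).to_numpy()
            ji = sub["year"].map(j_pos).to_numpy()
            if regime == "irrigated":
                arrays["p"][vi, ii, ji] = sub["yield"].to_numpy()
            elif regime == "rainfed":
                arrays["a"][vi, ii, ji] = sub["yield"].to_numpy()
                arrays["div"][vi, ii, ji] = sub["div"].to_numpy()
                arrays["dir"][vi, ii, ji] = sub["dir"].to_numpy()
            else:
                raise SchemaError(f"unknown water regime {regime!r}")
        for name, arr in arrays.items():
            if np.any(np.isnan(arr)):
                raise SchemaError(f"environment {env_id}: incomplete {name} factorial")
        doys = (
            np.asarray(sowing_doys)
            if sowing_doys is not None
            else 1 + 15 * (sowing - 1)  # default 15-day calendar
        )
        cube = GEICube(
            env_id=env_id,
            varieties=varieties,
            sowing_doys=np.asarray(doys),
            years=years,
            **arrays,
        )
        cube.validate()
        cubes[env_id] = cube
    return cubes


# -- environment metadata ----------------------------------------------------


def write_environments_csv(environments: list[EnvironmentParams], path) -> None:
    df = pd.DataFrame(
        {
            "env_id": [e.env_id for e in environments],
            "lon": [e.lon for e in environments],
            "lat": [e.lat for e in environments],
            "true_label": [e.true_label or "" for e in environments],
        }
    )
    _write_csv(df, path)


def read_environments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, ["env_id", "lon", "lat", "true_label"], "environment table")
    return df


def write_environments_geojson(environments: list[EnvironmentParams], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [e.lon, e.lat]},
            "properties": {"env_id": e.env_id, "true_label": e.true_label},
        }
        for e in environments
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


# -- stage tables ------------------------------------------------------------


def write_best_seasons(best: dict[str, BestSeason], path) -> None:
    df = pd.DataFrame(
        [
            {"env_id": b.env_id, "sowing_index": b.sowing_index, "sowing_doy": b.sowing_doy, "ry": b.ry, "cv": b.cv}
            for b in best.values()
        ],
        columns=BEST_SEASON_COLUMNS,
    )
    _write_csv(df, path)


def read_best_seasons(path) -> dict[str, BestSeason]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BEST_SEASON_COLUMNS, "best-season table")
    return {
        r.env_id: BestSeason(
            env_id=r.env_id,
            sowing_index=int(r.sowing_index),
            sowing_doy=int(r.sowing_doy),
            ry=float(r.ry),
            cv=float(r.cv),
        )
        for r in df.itertuples()
    }


def write_classification(table: pd.DataFrame, coords: pd.DataFrame | None, path) -> None:
    """Per-environment TPE table; joins lon/lat from ``coords`` if given."""
    df = table.copy()
    if coords is not None:
        df = df.merge(coords[["env_id", "lon", "lat"]], on="env_id", how="left")
    else:
        df["lon"] = np.nan
        df["lat"] = np.nan
    _write_csv(df[CLASSIFICATION_COLUMNS], path)


def read_classification(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CLASSIFICATION_COLUMNS, "classification table")
    return df


def classification_geojson(table: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.lon), float(r.lat)]},
            "properties": {"env_id": r.env_id, "label": r.label, "f75": float(r.f75)},
        }
        for r in table.itertuples()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def write_indicators(table: pd.DataFrame, path) -> None:
    _require_columns(table, INDICATOR_COLUMNS, "indicator table")
    _write_csv(table[INDICATOR_COLUMNS], path)


def read_indicators(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INDICATOR_COLUMNS, "indicator table")
    return df


def write_ranks(ranks: pd.DataFrame, path) -> None:
    _write_csv(ranks.reset_index(names="variety"), path)


def write_paired_series(df: pd.DataFrame, path) -> None:
    _require_columns(df, PAIRED_COLUMNS, "paired-series table")
    _write_csv(df[PAIRED_COLUMNS], path)


def read_paired_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PAIRED_COLUMNS, "paired-series table")
    return df
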