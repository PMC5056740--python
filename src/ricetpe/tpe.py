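"""Drought-based TPE classification of environments.

Each environment is assigned one of nine target-population-of-environment
classes from its best rainfed season: a severity letter from the frequency
f75 at which rainfed yield falls below 75% of irrigated yield (L mild < 25%,
M moderate 25-50%, S severe >= 50%) crossed with a drought-timing digit from
the mean stage drought indices (1 vegetative if av < ar, 2 reproductive if
ar < 0.9 av, 3 mixed otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import (
    CombinedPanels,
    SeasonSlice,
    best_season_slice,
    clean_unsuitable_dates,
    panels_from_cube,
    select_best_season,
)
from .synthetic import GEICube

__all__ = [
    "TPE_LABELS",
    "TPELabel",
    "f75_frequency",
    "severity_class",
    "timing_class",
    "classify_environment",
    "classify_grid",
    "class_proportions",
    "genotype_count_sensitivity",
    "suitability_map",
]

#: The full 9-class taxonomy: severity {L, M, S} x timing {1, 2, 3}.
TPE_LABELS = tuple(f"{s}{t}" for s in "LMS" for t in "123")

F75_RATIO = 0.75
SEVERITY_BOUNDS = (0.25, 0.50)  # lower bounds of M and S (inclusive)
TIMING_FACTOR = 0.90


@dataclass(frozen=True)
class TPELabel:
    env_id: str
    severity: str  # L, M or S
    timing: int  # 1 vegetative, 2 reproductive, 3 mixed
    f75: float
    av_bar: float
    ar_bar: float

    @property
    def label(self) -> str:
        return f"{self.severity}{self.timing}"


def f75_frequency(slice_: SeasonSlice, ratio: float = F75_RATIO) -> float:
    """Fraction of (year, variety) pairs with rainfed/irrigated yield < ratio.

    Strict inequality: a pair exactly at the threshold does not count.
    """
    if slice_.ay_jv.size == 0:
        raise ValueError(f"environment {slice_.env_id}: empty best-season slice")
    if np.any(slice_.py_jv <= 0):
        raise ValueError(f"environment {slice_.env_id}: irrigated yield must be > 0 after cleaning")
    return float(np.mean(slice_.ay_jv / slice_.py_jv < ratio))


def severity_class(f75: float, bounds: tuple[float, float] = SEVERITY_BOUNDS) -> str:
    """S for f75 >= 0.5, M for 0.25 <= f75 < 0.5, L for f75 < 0.25."""
    if not 0.0 <= f75 <= 1.0:
        raise ValueError(f"f75 must lie in [0, 1], got {f75}")
    m_lo, s_lo = bounds
    if f75 >= s_lo:
        return "S"
    if f75 >= m_lo:
        return "M"
    return "L"


def timing_class(av_bar: float, ar_bar: float, factor: float = TIMING_FACTOR) -> int:
    """1 if av < ar (vegetative), else 2 if ar < factor*av (reproductive), else 3.

    Evaluated in this order, so an environment with no stress at all
    (av = ar = 1) falls through to the mixed class; the taxonomy has no
    separate no-drought class.
    """
    for name, x in (("av_bar", av_bar), ("ar_bar", ar_bar)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {x}")
    if av_bar < ar_bar:
        return 1
    if ar_bar < factor * av_bar:
        return 2
    return 3


def classify_environment(
    slice_: SeasonSlice,
    *,
    ratio: float = F75_RATIO,
    bounds: tuple[float, float] = SEVERITY_BOUNDS,
    factor: float = TIMING_FACTOR,
) -> TPELabel:
    """TPE class of one environment from its best-season slice."""
    f75 = f75_frequency(slice_, ratio)
    av_bar = float(slice_.av_jv.mean())
    ar_bar = float(slice_.ar_jv.mean())
    return TPELabel(
        env_id=slice_.env_id,
        severity=severity_class(f75, bounds),
        timing=timing_class(av_bar, ar_bar, factor),
        f75=f75,
        av_bar=av_bar,
        ar_bar=ar_bar,
    )


def classify_grid(
    slices: dict[str, SeasonSlice],
    *,
    ratio: float = F75_RATIO,
    bounds: tuple[float, float] = SEVERITY_BOUNDS,
    factor: float = TIMING_FACTOR,
) -> pd.DataFrame:
    """Classify every environment; returns a tidy per-environment table."""
    rows = []
    for env_id, s in slices.items():
        lab = classify_environment(s, ratio=ratio, bounds=bounds, factor=factor)
        rows.append(
            {
                "env_id": env_id,
                "label": lab.label,
                "severity": lab.severity,
                "timing": lab.timing,
                "f75": lab.f75,
                "av_bar": lab.av_bar,
                "ar_bar": lab.ar_bar,
            }
        )
    return pd.DataFrame(rows, columns=["env_id", "label", "severity", "timing", "f75", "av_bar", "ar_bar"])


def class_proportions(table: pd.DataFrame) -> pd.Series:
    """Share of environments per TPE class (all nine classes, zeros kept)."""
    counts = table["label"].value_counts()
    props = pd.Series(0.0, index=list(TPE_LABELS), name="proportion")
    if len(table):
        props.update(counts / len(table))
    return props


def _slices_for_subset(panels: CombinedPanels, subset: np.ndarray) -> SeasonSlice:
    """Best-season slice after restricting the variety axis to ``subset``."""
    sub = CombinedPanels(
        env_id=panels.env_id,
        varieties=[panels.varieties[v] for v in subset],
        sowing_index=panels.sowing_index,
        sowing_doys=panels.sowing_doys,
        years=panels.years,
        py=panels.py[subset],
        ay=panels.ay[subset],
        av=panels.av[subset],
        ar=panels.ar[subset],
    )
    return best_season_slice(sub, select_best_season(sub))


def genotype_count_sensitivity(
    cubes: dict[str, GEICube],
    subset_sizes: list[int],
    n_replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """How the TPE class mix shifts with the number of genotypes used.

    For each subset size, varieties are repeatedly subsampled without
    replacement, the best season is re-selected and every environment
    reclassified from the subset alone.  Returns, per (size, class), the
    mean proportion over replicates and its standard deviation across
    replicates (the dispersion that shrinks as the panel grows).
    """
    if not cubes:
        raise ValueError("no environments supplied")
    panels = {k: clean_unsuitable_dates(panels_from_cube(c)) for k, c in cubes.items()}
    n_var = len(next(iter(panels.values())).varieties)
    for size in subset_sizes:
        if size < 1 or size > n_var:
            raise ValueError(f"subset size {size} outside 1..{n_var}")

    rng = np.random.default_rng(int(seed) % (2**31))
    records = []
    for size in subset_sizes:
        props = np.zeros((n_replicates, len(TPE_LABELS)))
        n_rep = 1 if size == n_var else n_replicates  # full panel: no sampling variation
        for rep in range(n_rep):
            subset = np.sort(rng.choice(n_var, size=size, replace=False))
            labels = [
                classify_environment(_slices_for_subset(p, subset)).label
                for p in panels.values()
            ]
            counts = pd.Series(labels).value_counts()
            for c, lab in enumerate(TPE_LABELS):
                props[rep, c] = counts.get(lab, 0) / len(labels)
        props = props[:n_rep]
        for c, lab in enumerate(TPE_LABELS):
            records.append(
                {
                    "n_genotypes": size,
                    "label": lab,
                    "mean_proportion": float(props[:, c].mean()),
                    "sd_proportion": float(props[:, c].std(ddof=0)) if n_rep > 1 else 0.0,
                }
            )
    return pd.DataFrame(records)


def suitability_map(
    slices: dict[str, SeasonSlice],
    focal_variety: str,
    check_varieties: list[str],
    thresholds: tuple[float, float] = (0.25, 1.0),
) -> pd.DataFrame:
    """Per-environment dissemination-suitability score of a focal variety.

    Score = the focal variety's mean best-season rainfed yield minus the
    best check's, in t/ha; categorised low/medium/high by the two
    thresholds.  A heuristic screening score, not a published metric.
    """
    lo, hi = thresholds
    rows = []
    for env_id, s in slices.items():
        names = list(s.varieties)
        if focal_variety not in names:
            raise KeyError(f"focal variety {focal_variety!r} absent in {env_id}")
        missing = [c for c in check_varieties if c not in names]
        if missing:
            raise KeyError(f"check varieties {missing} absent in {env_id}")
        means = s.ay_jv.mean(axis=0)  # per variety
        focal = means[names.index(focal_variety)]
        best_check = max(means[names.index(c)] for c in check_varieties)
        score = float(focal - best_check)
        category = "high" if score >= hi else ("medium" if score >= lo else "low")
        rows.append({"env_id": env_id, "score": score, "category": category})
    return pd.DataFrame(rows, columns=["env_id", "score", "category"])
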