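"""Variety ranking by hierarchical clustering of the stability indicators.

Varieties are clustered on the z-scored five-indicator profile (gamma is
negated first so that *lower is better* for every column), with Ward
linkage on Euclidean distance, and the tree is cut at five groups.  Groups
are ordered by mean standardised desirability, so every member of the best
group gets rank 1 and of the worst gets rank 5.  An adaptability table
repeats this per pooled drought-severity scope (S/M/L), pooled timing scope
(V/R/V+R) and over all environments ("Sum" column).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .stability import indicator_table
from .matrices import SeasonSlice

__all__ = [
    "INDICATOR_COLUMNS",
    "hierarchical_rank",
    "adaptability_table",
    "rank_correlation",
]

INDICATOR_COLUMNS = ("gamma", "delta", "lambda", "phi", "psi")


def hierarchical_rank(
    table: pd.DataFrame,
    n_groups: int = 5,
    method: str = "ward",
) -> pd.Series:
    """Rank varieties 1 (best) .. n_groups (worst) by clustering.

    ``table`` is indexed by variety with the five indicator columns.  If
    there are fewer distinct profiles than groups the clusters collapse and
    the worst rank actually used is smaller than ``n_groups``.
    """
    if table.empty:
        raise ValueError("empty indicator table")
    x = table.loc[:, list(INDICATOR_COLUMNS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("indicator table contains non-finite values")

    desir = x.copy()
    desir[:, 0] = -desir[:, 0]  # high gamma is good; flip so lower = better
    sd = desir.std(axis=0, ddof=0)
    z = (desir - desir.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    # cluster distinct profiles only, so ties share a group and a table of
    # identical varieties collapses to a single rank
    uniq, inverse = np.unique(z, axis=0, return_inverse=True)
    if len(uniq) == 1:
        groups = np.ones(len(table), dtype=int)
    else:
        t = min(n_groups, len(uniq))
        uniq_groups = fcluster(linkage(uniq, method=method), t=t, criterion="maxclust")
        groups = uniq_groups[inverse]

    # order clusters by mean desirability (ascending = best first);
    # break ties toward the cluster with higher mean gamma
    scores = []
    for g in np.unique(groups):
        mask = groups == g
        scores.append((float(z[mask].mean()), float(-x[mask, 0].mean()), g))
    order = {g: rank for rank, (_, _, g) in enumerate(sorted(scores), start=1)}
    return pd.Series([order[g] for g in groups], index=table.index, name="rank")


_SCOPE_COLUMNS = [("S", "S"), ("M", "M"), ("L", "L"), ("1", "V"), ("2", "R"), ("3", "V+R"), ("ALL", "Sum")]


def adaptability_table(
    slices: dict[str, SeasonSlice],
    env_labels: dict[str, str],
    n_groups: int = 5,
    method: str = "ward",
) -> pd.DataFrame:
    """Variety x scope rank table (severity S/M/L, timing V/R/V+R, Sum).

    Severity scopes pool environments sharing the severity letter, timing
    scopes the timing digit; "Sum" is the rank over all environments.
    Scopes with no environments are omitted.
    """
    scopes = [s for s, _ in _SCOPE_COLUMNS]
    tidy = indicator_table(slices, env_labels, scopes)
    out = {}
    for scope, column in _SCOPE_COLUMNS:
        sub = tidy[tidy["scope"] == scope]
        if sub.empty:
            continue
        ranks = hierarchical_rank(sub.set_index("variety"), n_groups=n_groups, method=method)
        out[column] = ranks
    return pd.DataFrame(out)


def rank_correlation(order_a, order_b) -> tuple[float, float]:
    """Pearson r and R^2 between two equal-length rank vectors.

    On rank permutations the Pearson correlation coincides with Spearman's
    rho, so this is the concordance of two orderings of the same varieties.
    """
    a = np.asarray(order_a, dtype=float)
    b = np.asarray(order_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rank vectors must be one-dimensional and equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("rank vectors must have nonzero variance")
    r = float(pearsonr(a, b).statistic)
    return r, r * r
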