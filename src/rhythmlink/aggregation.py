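"""Fisher-method aggregation of correlation cells into per-feature and
per-parameter scores.

Cell p-values are combined with Fisher's method (X = -2*sum(ln p), compared
to a chi-square with 2k degrees of freedom); the aggregated correlation C is
the mean of the cell coefficients that are individually significant at alpha
(undefined — a blank cell — when none are), and the significance score S is
-log10 of the combined p, capped.  Aggregation runs per sensor feature
(across rhythm parameters) and per rhythm parameter (across features) within
each week, then hierarchically across weeks: the overall combined p is
Fisher over the weekly combined p's and the overall C the mean of the
defined weekly C's.  A flat variant that pools cell p-values across weeks is
available via ``method="flat"``.

Fisher's method assumes independent tests; correlation cells sharing a
feature or parameter are not independent, so combined p-values are read as
ranking scores, not literal error rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AggregateScore",
    "fisher_combine",
    "aggregate_cells",
    "combine_weeks",
    "aggregate_all",
    "rank_report",
    "score_matrix",
]

DEFAULT_ALPHA = 0.05
DEFAULT_S_CAP = 16.0
_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class AggregateScore:
    """Combined correlation C and significance S for one key and scope."""

    axis: str  # "feature" or "parameter"
    key: str
    scope: object  # week index or "overall"
    c_agg: float | None
    s_score: float
    fisher_stat: float
    combined_p: float
    n_cells: int
    n_significant: int


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: X = -2*sum(ln p_i) ~ chi-square with 2k df.

    A single p-value is returned unchanged (the chi-square(2) survival
    function at -2*ln p is exactly p, so the identity is made exact rather
    than round-tripped through exp(log(p))).  Zero p-values are clamped to
    the smallest positive float.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.where(p == 0, _TINY_P, p)
    x = float(-2.0 * np.log(p).sum())
    if p.size == 1:
        return x, float(p[0])
    return x, float(stats.chi2.sf(x, 2 * p.size))


def _s_score(combined_p: float, s_cap: float) -> float:
    if combined_p <= 0:
        return s_cap
    return min(s_cap, -math.log10(combined_p))


def aggregate_cells(
    cells: pd.DataFrame,
    axis: str,
    key: str,
    scope,
    alpha: float = DEFAULT_ALPHA,
    s_cap: float = DEFAULT_S_CAP,
) -> AggregateScore:
    """Combine the cells sharing one axis key within one scope (week).

    ``cells`` needs columns r and p.  C is the mean r over cells with
    p < alpha (None when no cell is significant, rendered blank downstream);
    the combined p is Fisher over *all* cell p's.
    """
    if cells.empty:
        raise ValueError("no cells to aggregate")
    fisher_stat, combined_p = fisher_combine(cells["p"].to_numpy())
    significant = cells[cells["p"] < alpha]
    c_agg = float(significant["r"].mean()) if len(significant) else None
    return AggregateScore(
        axis=axis,
        key=key,
        scope=scope,
        c_agg=c_agg,
        s_score=_s_score(combined_p, s_cap),
        fisher_stat=fisher_stat,
        combined_p=combined_p,
        n_cells=len(cells),
        n_significant=len(significant),
    )


def combine_weeks(
    weekly: Iterable[AggregateScore], s_cap: float = DEFAULT_S_CAP
) -> AggregateScore:
    """Hierarchical cross-week combination for one key.

    Fisher over the weekly combined p's; overall C is the mean of the weekly
    C's that are defined (all-blank weeks give an undefined overall C while S
    is still computed).
    """
    weekly = list(weekly)
    if not weekly:
        raise ValueError("no weekly scores to combine")
    keys = {(w.axis, w.key) for w in weekly}
    if len(keys) != 1:
        raise ValueError(f"weekly scores mix keys: {keys}")
    axis, key = weekly[0].axis, weekly[0].key
    fisher_stat, combined_p = fisher_combine([w.combined_p for w in weekly])
    defined = [w.c_agg for w in weekly if w.c_agg is not None]
    c_agg = float(np.mean(defined)) if defined else None
    return AggregateScore(
        axis=axis,
        key=key,
        scope="overall",
        c_agg=c_agg,
        s_score=_s_score(combined_p, s_cap),
        fisher_stat=fisher_stat,
        combined_p=combined_p,
        n_cells=sum(w.n_cells for w in weekly),
        n_significant=sum(w.n_significant for w in weekly),
    )


def _flat_overall(
    sub: pd.DataFrame, axis: str, key: str, alpha: float, s_cap: float
) -> AggregateScore:
    return aggregate_cells(sub, axis, key, "overall", alpha=alpha, s_cap=s_cap)


def aggregate_all(
    cells: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    s_cap: float = DEFAULT_S_CAP,
    method: str = "hierarchical",
) -> pd.DataFrame:
    """Weekly and overall aggregate scores for both axes.

    ``cells`` is the frame from :func:`correlation.cells_to_frame`.  Returns
    one row per (axis, key, scope) with C blank (NaN) where no cell was
    significant.
    """
    if method not in ("hierarchical", "flat"):
        raise ValueError("method must be 'hierarchical' or 'flat'")
    scores: list[AggregateScore] = []
    for axis, column in (("feature", "feature"), ("parameter", "parameter")):
        for key, key_cells in cells.groupby(column, sort=True):
            weekly = [
                aggregate_cells(sub, axis, str(key), int(week), alpha=alpha, s_cap=s_cap)
                for week, sub in key_cells.groupby("week", sort=True)
            ]
            scores.extend(weekly)
            if method == "hierarchical":
                scores.append(combine_weeks(weekly, s_cap=s_cap))
            else:
                scores.append(_flat_overall(key_cells, axis, str(key), alpha, s_cap))
    return pd.DataFrame(
        [
            {
                "axis": s.axis,
                "key": s.key,
                "scope": s.scope,
                "C": np.nan if s.c_agg is None else s.c_agg,
                "S": s.s_score,
                "fisher_stat": s.fisher_stat,
                "combined_p": s.combined_p,
                "n_cells": s.n_cells,
                "n_significant": s.n_significant,
            }
            for s in scores
        ],
        columns=["axis", "key", "scope", "C", "S", "fisher_stat", "combined_p",
                 "n_cells", "n_significant"],
    )


def rank_report(scores: pd.DataFrame, top_k: int = 10) -> dict[str, pd.DataFrame]:
    """Top-k overall rankings per axis, by |C| and by S.

    Undefined C ranks last; ties break lexicographically on the key name.
    Keys of the returned dict: '<axis>_by_C' and '<axis>_by_S'.
    """
    out: dict[str, pd.DataFrame] = {}
    overall = scores[scores["scope"] == "overall"]
    for axis in ("feature", "parameter"):
        sub = overall[overall["axis"] == axis].copy()
        sub["absC"] = sub["C"].abs()
        by_c = sub.sort_values(
            by=["absC", "key"], ascending=[False, True], na_position="last"
        ).drop(columns="absC").head(top_k).reset_index(drop=True)
        by_s = sub.sort_values(
            by=["S", "key"], ascending=[False, True]
        ).drop(columns="absC").head(top_k).reset_index(drop=True)
        out[f"{axis}_by_C"] = by_c
        out[f"{axis}_by_S"] = by_s
    return out


def score_matrix(scores: pd.DataFrame, axis: str, value: str = "C") -> pd.DataFrame:
    """Keys x scopes matrix of C or S (heat-map layout; blanks stay NaN)."""
    sub = scores[scores["axis"] == axis]
    matrix = sub.pivot(index="key", columns="scope", values=value)
    week_cols = sorted(c for c in matrix.columns if c != "overall")
    cols = week_cols + (["overall"] if "overall" in matrix.columns else [])
    return matrix[cols]
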