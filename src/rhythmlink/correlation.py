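"""Per-cell Pearson correlation between rhythm parameters and productivity.

For each (sensor feature, rhythm parameter, survey week) the rhythm-parameter
values across participants are paired with the participants' weekly mean
productivity scores, both min-max normalized, and summarized by the sample
Pearson coefficient with its two-tailed t-test p-value.  Min-max scaling is
an affine map, so it cannot change r or p; it is kept because the analysis
pipeline specifies it for scale comparability.  Cells with too few
observations (n <= min_n, default 28) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationCell",
    "DegenerateScaleError",
    "minmax_normalize",
    "correlation_cell",
    "correlation_table",
    "cells_to_frame",
]

DEFAULT_MIN_N = 28
ID_COLUMNS = ("participant_id", "feature", "week", "n_obs")


class DegenerateScaleError(ValueError):
    """A vector with zero range cannot be normalized or correlated."""


@dataclass(frozen=True)
class CorrelationCell:
    feature_name: str
    parameter_name: str
    week: int
    r: float
    p: float
    n: int


def minmax_normalize(values) -> np.ndarray:
    """(x - min) / (max - min); raises DegenerateScaleError on constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise DegenerateScaleError("constant vector has no min-max scale")
    return (x - lo) / (hi - lo)


def correlation_cell(param_values, productivity_values) -> tuple[float, float, int]:
    """Pearson r, two-tailed p and pair count for one cell.

    Inputs are participant-aligned; pairs with a missing side are dropped.
    The p-value is the classical t test, t = r*sqrt((n-2)/(1-r^2)) on n-2
    degrees of freedom (p = 0 at |r| = 1).
    """
    x = np.asarray(param_values, dtype=float)
    y = np.asarray(productivity_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateScaleError("zero variance on one side of the correlation")
    x = minmax_normalize(x)
    y = minmax_normalize(y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def correlation_table(
    rhythms: pd.DataFrame,
    weekly_scores: pd.DataFrame,
    min_n: int = DEFAULT_MIN_N,
    parameters: Iterable[str] | None = None,
) -> tuple[list[CorrelationCell], pd.DataFrame]:
    """All (feature, parameter, week) cells with more than ``min_n`` pairs.

    ``rhythms`` is the wide per-fit table from :func:`cosinor.fits_to_frame`;
    ``weekly_scores`` has participant_id, week, mean_score.  Returns the
    retained cells and a log of excluded cells with the exclusion reason.
    """
    if parameters is None:
        parameters = [c for c in rhythms.columns if c not in ID_COLUMNS]
    merged = rhythms.merge(
        weekly_scores[["participant_id", "week", "mean_score"]],
        on=["participant_id", "week"],
        how="inner",
    )
    cells: list[CorrelationCell] = []
    log_rows = []
    for (feature, week), sub in merged.groupby(["feature", "week"], sort=True):
        for param in parameters:
            entry = {"feature": feature, "parameter": param, "week": week}
            x = sub[param].to_numpy(dtype=float)
            y = sub["mean_score"].to_numpy(dtype=float)
            n_complete = int((~(np.isnan(x) | np.isnan(y))).sum())
            if n_complete <= min_n:
                log_rows.append({**entry, "n": n_complete, "reason": "too-few-observations"})
                continue
            try:
                r, p, n = correlation_cell(x, y)
            except DegenerateScaleError:
                log_rows.append({**entry, "n": n_complete, "reason": "degenerate-scale"})
                continue
            cells.append(CorrelationCell(feature, param, int(week), r, p, n))
    log = pd.DataFrame(log_rows, columns=["feature", "parameter", "week", "n", "reason"])
    return cells, log


def cells_to_frame(cells: Iterable[CorrelationCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": c.feature_name,
                "parameter": c.parameter_name,
                "week": c.week,
                "r": c.r,
                "p": c.p,
                "n": c.n,
            }
            for c in cells
        ],
        columns=["feature", "parameter", "week", "r", "p", "n"],
    )
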