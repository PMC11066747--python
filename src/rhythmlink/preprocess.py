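"""Cleaning of hourly streams: hourly statistics, missingness profiling,
linear-interpolation imputation, and the 20%-missing discard rule.

The imputation rule fills each interior run of missing hours by the straight
line through its two observed anchors, v_t = v_a + (t-a)*(v_b-v_a)/(b-a);
runs touching the series boundary (one anchor only) are filled with the
nearest observed value, which adds no trend at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import HourlySeries

__all__ = [
    "MissingnessProfile",
    "hourly_statistics",
    "missingness_profile",
    "impute_series",
    "select_streams",
]


@dataclass(frozen=True)
class MissingnessProfile:
    fraction_missing: float
    block_lengths: tuple[int, ...]
    mean_block: float | None
    sd_block: float | None


def hourly_statistics(
    events: pd.DataFrame,
    participant_id: str = "unknown",
    feature_name: str = "feature",
    value_column: str = "value",
    hour_column: str = "hour",
) -> dict[str, HourlySeries]:
    """Aggregate timestamped events into five hourly statistic streams.

    ``events`` needs an hour column (float hours from the reference midnight,
    or anything ``//1``-able to an hour index) and a numeric value column.
    Returns min/max/mean/std/count series over the full observed hour span;
    hours with zero events are missing in every output, and the sample SD is
    missing for hours with a single event.
    """
    if events.empty:
        raise ValueError("no events provided")
    values = pd.to_numeric(events[value_column], errors="coerce")
    bad = values.isna() & events[value_column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric value in events row {events.index[row]}")
    hours = np.floor(events[hour_column].to_numpy(dtype=float)).astype(np.int64)
    frame = pd.DataFrame({"hour": hours, "value": values.to_numpy(dtype=float)})

    grouped = frame.groupby("hour")["value"]
    stats = pd.DataFrame(
        {
            "min": grouped.min(),
            "max": grouped.max(),
            "mean": grouped.mean(),
            "std": grouped.std(ddof=1),  # NaN when n == 1
            "count": grouped.size().astype(float),
        }
    )
    full_index = np.arange(hours.min(), hours.max() + 1)
    stats = stats.reindex(full_index)

    out = {}
    for stat in ("min", "max", "mean", "std", "count"):
        vals = stats[stat].to_numpy(dtype=float)
        out[stat] = HourlySeries(
            participant_id=participant_id,
            feature_name=f"{feature_name}_{stat}",
            hours=full_index,
            values=vals,
            missing_mask=np.isnan(vals),
        )
    return out


def _missing_blocks(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in the mask."""
    padded = np.concatenate(([0], mask.astype(int), [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return [int(b - a) for a, b in zip(starts, stops)]


def missingness_profile(series: HourlySeries) -> MissingnessProfile:
    """Fraction missing plus the length distribution of missing-hour blocks."""
    blocks = _missing_blocks(series.missing_mask)
    mean_block = float(np.mean(blocks)) if blocks else None
    sd_block = float(np.std(blocks, ddof=1)) if len(blocks) >= 2 else None
    return MissingnessProfile(
        fraction_missing=series.fraction_missing,
        block_lengths=tuple(blocks),
        mean_block=mean_block,
        sd_block=sd_block,
    )


def impute_series(series: HourlySeries) -> HourlySeries:
    """Fill every missing hour: linear interpolation between observed
    anchors, nearest observed value for leading/trailing runs.

    np.interp implements exactly this (piecewise-linear interior, constant
    extrapolation at the edges).  Observed values pass through unchanged.
    """
    observed = ~series.missing_mask
    if not observed.any():
        raise ValueError(
            f"cannot impute all-missing series "
            f"{series.participant_id}/{series.feature_name}"
        )
    out = series.copy()
    if observed.all():
        return out
    t = series.hours.astype(float)
    filled = np.interp(t, t[observed], series.values[observed])
    out.values = np.where(observed, series.values, filled)
    out.missing_mask = np.zeros_like(series.missing_mask)
    return out


def select_streams(
    series_set, max_missing: float = 0.20
) -> tuple[list[HourlySeries], pd.DataFrame]:
    """Impute and keep streams with strictly less than ``max_missing``
    fraction of missing hours; discard the rest.

    Returns the retained (imputed) streams and a log with one row per input
    stream recording its missing fraction and the decision.
    """
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must be in (0, 1]")
    retained: list[HourlySeries] = []
    rows = []
    for s in series_set:
        frac = s.fraction_missing
        keep = frac < max_missing
        rows.append(
            {
                "participant_id": s.participant_id,
                "feature": s.feature_name,
                "fraction_missing": frac,
                "decision": "retained" if keep else "discarded",
            }
        )
        if keep:
            retained.append(impute_series(s))
    log = pd.DataFrame(
        rows, columns=["participant_id", "feature", "fraction_missing", "decision"]
    )
    return retained, log
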