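"""Hourly time-series container and CSV round-trip.

The unit of rhythm modeling is one participant x feature stream sampled on an
integer hour grid (hour 0 = local midnight of study day 1, intervals half-open
[h, h+1)).  Missing hours carry NaN values and a True entry in the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["HourlySeries", "read_streams", "write_streams"]

STREAM_COLUMNS = ["participant_id", "feature", "hour", "value", "missing"]


@dataclass
class HourlySeries:
    """One participant x feature hourly stream with a missingness mask.

    Parameters
    ----------
    participant_id, feature_name : str
        Identity of the stream.
    hours : array of int
        Strictly increasing hour indices counted from a reference midnight.
    values : array of float
        Signal values; NaN where ``missing_mask`` is True.
    missing_mask : array of bool
        True at hours with no observation.
    """

    participant_id: str
    feature_name: str
    hours: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (len(self.hours) == len(self.values) == len(self.missing_mask)):
            raise ValueError("hours, values and missing_mask must have equal length")
        if len(self.hours) == 0:
            raise ValueError("empty series")
        if np.any(np.diff(self.hours) <= 0):
            raise ValueError("hours must be strictly increasing")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing values must be finite")

    @property
    def n_hours(self) -> int:
        return len(self.hours)

    @property
    def fraction_missing(self) -> float:
        return float(self.missing_mask.mean())

    def copy(self) -> "HourlySeries":
        return replace(
            self,
            hours=self.hours.copy(),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
        )

    def window(self, start_hour: int, stop_hour: int) -> "HourlySeries":
        """Slice to hours in the half-open range [start_hour, stop_hour)."""
        sel = (self.hours >= start_hour) & (self.hours < stop_hour)
        if not sel.any():
            raise ValueError(
                f"window [{start_hour}, {stop_hour}) contains no hours of the series"
            )
        return replace(
            self,
            hours=self.hours[sel],
            values=self.values[sel],
            missing_mask=self.missing_mask[sel],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "feature": self.feature_name,
                "hour": self.hours,
                "value": self.values,
                "missing": self.missing_mask.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HourlySeries":
        pid = frame["participant_id"].iloc[0]
        feat = frame["feature"].iloc[0]
        frame = frame.sort_values("hour")
        return cls(
            participant_id=str(pid),
            feature_name=str(feat),
            hours=frame["hour"].to_numpy(),
            values=frame["value"].to_numpy(dtype=float),
            missing_mask=frame["missing"].to_numpy(dtype=bool),
        )


def write_streams(streams: Iterable[HourlySeries], path) -> pd.DataFrame:
    """Write streams to one long CSV (participant_id,feature,hour,value,missing)."""
    table = pd.concat([s.to_frame() for s in streams], ignore_index=True)
    table.to_csv(path, index=False)
    return table


def read_streams(path) -> list[HourlySeries]:
    """Read the long CSV written by :func:`write_streams` back into series."""
    table = pd.read_csv(path)
    missing = set(STREAM_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"stream table missing columns: {sorted(missing)}")
    out = []
    for _, group in table.groupby(["participant_id", "feature"], sort=True):
        out.append(HourlySeries.from_frame(group))
    return out
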