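"""Container for geolocator-style tracking fixes.

A TrackSet wraps a tidy DataFrame of fixes (bird_id, colony, timestamp,
lon, lat) restricted to the austral-summer non-breeding window (October
through February) with at most two fixes per bird-day, the cadence of
light-level geolocators (one midday and one midnight position).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geospatial import normalize_lon

#: calendar months of the non-breeding period, in season order
SEASON_MONTHS = (10, 11, 12, 1, 2)

REQUIRED_COLUMNS = ("bird_id", "colony", "timestamp", "lon", "lat")


class TrackSet:
    """Validated set of tracking fixes with derived month tags.

    Parameters
    ----------
    records : pandas.DataFrame
        Must contain columns ``bird_id, colony, timestamp, lon, lat``.
        Timestamps are parsed with :func:`pandas.to_datetime`; longitudes
        are normalized into [-180, 180).
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"track records missing columns: {missing}")
        df = records.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df["lon"] = normalize_lon(df["lon"].to_numpy(dtype=float))
        df["lat"] = df["lat"].astype(float)
        if (df["lat"].abs() > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        df["month"] = df["timestamp"].dt.month.astype(int)
        bad_months = sorted(set(df["month"]) - set(SEASON_MONTHS))
        if bad_months:
            raise ValueError(
                f"fixes outside the October-February non-breeding window: months {bad_months}"
            )
        per_day = df.groupby(["bird_id", df["timestamp"].dt.date]).size()
        if (per_day > 2).any():
            raise ValueError("more than two fixes for a bird-day (geolocator cadence is 2/day)")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def months(self) -> list[int]:
        """Months present, in season (Oct..Feb) order."""
        present = set(self.df["month"])
        return [m for m in SEASON_MONTHS if m in present]

    @property
    def colonies(self) -> list[str]:
        return sorted(self.df["colony"].unique())

    def month_subset(self, month: int) -> pd.DataFrame:
        return self.df[self.df["month"] == month]

    def lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        return self.df["lon"].to_numpy(), self.df["lat"].to_numpy()

    def to_csv(self, path) -> None:
        cols = ["bird_id", "colony", "timestamp", "lon", "lat"]
        out = self.df[cols].copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrackSet":
        return cls(pd.read_csv(path))
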