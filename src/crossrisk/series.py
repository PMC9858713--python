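"""Daily environmental exposure series and their CSV representation.

An :class:`EnvironmentalSeries` is one region's contiguous daily record of
minimum/maximum temperature (degC), average/maximum relative humidity (%)
and average ozone concentration. It is a thin, validated wrapper around a
pandas DataFrame indexed by calendar day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .config import VARIABLES

__all__ = ["EnvironmentalSeries", "read_series_csv", "write_series_csv"]


class SeriesValidationError(ValueError):
    """Raised when a series violates its physical invariants."""


@dataclass
class EnvironmentalSeries:
    """One region's contiguous daily exposure record.

    Invariants enforced on construction: contiguous daily dates, per-day
    ``min_temp <= max_temp``, ``0 <= ave_rh <= max_rh <= 100`` and
    ``ave_o3 >= 0`` where present.
    """

    region: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            f = f.copy()
            f.index = pd.DatetimeIndex(pd.to_datetime(f.index))
        f = f.sort_index()
        missing = [v for v in VARIABLES if v not in f.columns]
        if missing:
            raise SeriesValidationError(f"series missing columns {missing}")
        n = len(f)
        if n == 0:
            raise SeriesValidationError("empty series")
        span = (f.index[-1] - f.index[0]).days + 1
        if span != n or f.index.has_duplicates:
            raise SeriesValidationError("series dates must be contiguous daily")
        if (f["min_temp"] > f["max_temp"]).any():
            raise SeriesValidationError("min_temp > max_temp on some day")
        rh = f[["ave_rh", "max_rh"]]
        if (rh < 0).any().any() or (rh > 100).any().any():
            raise SeriesValidationError("relative humidity outside [0, 100]")
        if (f["ave_rh"] > f["max_rh"]).any():
            raise SeriesValidationError("ave_rh > max_rh on some day")
        o3 = f["ave_o3"].dropna()
        if (o3 < 0).any():
            raise SeriesValidationError("negative ozone concentration")
        object.__setattr__(self, "frame", f)

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start_date(self) -> date:
        return self.frame.index[0].date()

    @property
    def end_date(self) -> date:
        return self.frame.index[-1].date()

    def covers(self, day: date) -> bool:
        return self.start_date <= day <= self.end_date

    def value(self, variable: str, day: date) -> float:
        """Scalar value of ``variable`` on ``day`` (KeyError if uncovered)."""
        return float(self.frame.at[pd.Timestamp(day), variable])

    def day_number(self, day: date) -> int:
        """Whole days elapsed since the series start (day 0 = first day)."""
        return (pd.Timestamp(day) - self.frame.index[0]).days


def write_series_csv(series_list, path: str | Path) -> None:
    """Write one or more series to the long CSV layout
    (``date,region,min_temp,max_temp,ave_rh,max_rh,ave_o3``)."""
    if isinstance(series_list, EnvironmentalSeries):
        series_list = [series_list]
    frames = []
    for s in series_list:
        f = s.frame.reset_index(names="date")
        f.insert(1, "region", s.region)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.6g")


def read_series_csv(path: str | Path) -> dict[str, EnvironmentalSeries]:
    """Read the long CSV layout back into per-region series."""
    raw = pd.read_csv(path, parse_dates=["date"])
    out: dict[str, EnvironmentalSeries] = {}
    for region, grp in raw.groupby("region", sort=True):
        f = grp.drop(columns="region").set_index("date")
        out[str(region)] = EnvironmentalSeries(region=str(region), frame=f)
    return out
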