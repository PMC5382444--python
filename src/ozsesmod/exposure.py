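"""ZCTA-level exposure assignment from gridded ozone fields.

Daily ambient 8-h maximum ozone is produced on a regular grid (e.g. a
12x12 km fused observation/chemical-transport field).  Health analyses run
at the ZIP Code Tabulation Area (ZCTA) level, so each ZCTA's daily value is
the area-weighted average of the grid cells it overlaps.  Short-term risk
models use the 3-day moving average (lag days 0-2) of the ZCTA series, and
the same moving average of city-level maximum temperature and mean dew
point for meteorological control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AreaWeightError",
    "MissingGridDataError",
    "ExposureSeries",
    "compute_area_weights",
    "fuse_grid_to_zcta",
    "moving_average_lag02",
    "build_exposure_series",
]


class AreaWeightError(ValueError):
    """Raised when an overlap table cannot be normalized into weights."""


class MissingGridDataError(ValueError):
    """Raised when the gridded field lacks a (date, cell) needed for fusion."""


def compute_area_weights(overlap: pd.DataFrame) -> pd.DataFrame:
    """Normalize a ZCTA-cell overlap-area table into fractional weights.

    Parameters
    ----------
    overlap : DataFrame with columns ``zcta``, ``cell``, ``area``
        ``area`` is the (unnormalized) area of the intersection between the
        ZCTA polygon and the grid cell, in any consistent unit.

    Returns
    -------
    DataFrame with columns ``zcta``, ``cell``, ``weight`` where weights are
    nonnegative and sum to 1 within each ZCTA.
    """
    required = {"zcta", "cell", "area"}
    if not required.issubset(overlap.columns):
        raise AreaWeightError(f"overlap table must have columns {sorted(required)}")
    if (overlap["area"] < 0).any():
        bad = overlap.loc[overlap["area"] < 0, "zcta"].unique()
        raise AreaWeightError(f"negative overlap areas for ZCTAs {list(bad)}")
    totals = overlap.groupby("zcta")["area"].sum()
    zero = totals.index[totals <= 0]
    if len(zero):
        raise AreaWeightError(f"zero total overlap area for ZCTAs {list(zero)}")
    out = overlap[["zcta", "cell"]].copy()
    out["weight"] = overlap["area"].to_numpy() / totals.reindex(overlap["zcta"]).to_numpy()
    return out


def fuse_grid_to_zcta(field: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Area-weight a gridded daily field onto ZCTAs.

    Parameters
    ----------
    field : DataFrame with columns ``date``, ``cell``, ``value`` (long format)
    weights : output of :func:`compute_area_weights`

    Returns
    -------
    Wide DataFrame indexed by date with one column per ZCTA; each entry is
    ``sum_cell weight * value`` and therefore lies within the min/max of the
    contributing cells on that date.
    """
    value_col = "value" if "value" in field.columns else field.columns[-1]
    wide = field.pivot(index="date", columns="cell", values=value_col)
    needed = weights["cell"].unique()
    missing_cells = [c for c in needed if c not in wide.columns]
    if missing_cells:
        raise MissingGridDataError(f"cells absent from field: {missing_cells}")
    sub = wide[needed]
    if sub.isna().any().any():
        stacked = sub.isna()
        pairs = [
            (d, c)
            for c in sub.columns
            for d in sub.index[stacked[c]]
        ][:20]
        raise MissingGridDataError(f"missing cell-days in gridded field (first 20): {pairs}")
    wmat = weights.pivot(index="cell", columns="zcta", values="weight").fillna(0.0)
    wmat = wmat.reindex(sub.columns).fillna(0.0)
    fused = pd.DataFrame(
        sub.to_numpy() @ wmat.to_numpy(), index=sub.index, columns=wmat.columns
    )
    fused.columns.name = "zcta"
    return fused


def moving_average_lag02(series: pd.Series | pd.DataFrame):
    """3-day moving average over lags 0-2: value at t = mean(x_t, x_{t-1}, x_{t-2}).

    The first two days (and any window containing a missing value) are NaN.
    Assumes a contiguous daily index.
    """
    return series.rolling(window=3, min_periods=3).mean()


@dataclass
class ExposureSeries:
    """Per-city exposure/meteorology bundle consumed by the stage-1 model.

    Attributes
    ----------
    o3 : wide DataFrame (date x zcta), daily 8-h max ozone in ppb
    o3_ma02 : same shape, 3-day moving average (lags 0-2)
    tmax_ma02, dew_ma02 : city-level daily Series of the 3-day moving
        averages of maximum temperature (F) and mean dew point (F)
    """

    o3: pd.DataFrame
    o3_ma02: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    tmax_ma02: pd.Series | None = None
    dew_ma02: pd.Series | None = None

    def __post_init__(self):
        if self.o3_ma02 is None:
            self.o3_ma02 = moving_average_lag02(self.o3)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.o3.index)

    def to_long(self) -> pd.DataFrame:
        """Long per-ZCTA exposure table (zcta, date, o3, o3_ma02)."""
        long = self.o3.stack().rename("o3").reset_index()
        long.columns = ["date", "zcta", "o3"]
        ma = self.o3_ma02.stack(future_stack=True).rename("o3_ma02").reset_index()
        ma.columns = ["date", "zcta", "o3_ma02"]
        return long.merge(ma, on=["date", "zcta"], how="left")


def build_exposure_series(
    field: pd.DataFrame,
    overlap: pd.DataFrame,
    met: pd.DataFrame | None = None,
) -> ExposureSeries:
    """Fuse a gridded ozone field onto ZCTAs and attach meteorology.

    ``met`` is a city-level daily table with columns ``date``, ``tmax``,
    ``dewpoint`` (already restricted to one city).
    """
    weights = compute_area_weights(overlap)
    fused = fuse_grid_to_zcta(field, weights)
    fused.index = pd.DatetimeIndex(fused.index)
    fused = fused.sort_index()
    tmax_ma = dew_ma = None
    if met is not None:
        m = met.copy()
        m["date"] = pd.DatetimeIndex(m["date"])
        m = m.set_index("date").sort_index()
        tmax_ma = moving_average_lag02(m["tmax"])
        dew_ma = moving_average_lag02(m["dewpoint"])
    return ExposureSeries(
        o3=fused,
        o3_ma02=moving_average_lag02(fused),
        tmax_ma02=tmax_ma,
        dew_ma02=dew_ma,
    )
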