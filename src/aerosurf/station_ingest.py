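"""Hourly station records -> validated station-day targets.

A civil day is fixed UTC-6 with no daylight-saving shifts.  A station-day
is retained only when at least ``min_hours`` distinct hours carry a valid
concentration; its targets are the mean and the maximum of the available
hourly values.  Seasons follow the Central-Mexico convention: two dry
seasons (cold: Nov-Feb, warm: Mar-May) and one rainy season (Jun-Oct).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

MIN_HOURS_DEFAULT = 18

SEASONS = ("cold_dry", "warm_dry", "rainy")

_MONTH_TO_SEASON = {
    11: "cold_dry", 12: "cold_dry", 1: "cold_dry", 2: "cold_dry",
    3: "warm_dry", 4: "warm_dry", 5: "warm_dry",
    6: "rainy", 7: "rainy", 8: "rainy", 9: "rainy", 10: "rainy",
}


def assign_season(date) -> str:
    """Season label for a date: cold_dry (Nov-Feb), warm_dry (Mar-May), rainy (Jun-Oct)."""
    if isinstance(date, (pd.Timestamp, _dt.date)):
        return _MONTH_TO_SEASON[date.month]
    raise TypeError(f"expected a date, got {type(date).__name__}")


def season_of_dates(dates: pd.DatetimeIndex | pd.Series) -> np.ndarray:
    """Vectorized :func:`assign_season` over a datetime index or series."""
    months = pd.DatetimeIndex(dates).month
    return np.array([_MONTH_TO_SEASON[m] for m in months])


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"station_id", "date", "hour", "pm25"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    dates = pd.to_datetime(records["date"])
    if getattr(dates.dt, "tz", None) is not None:
        raise ValueError(
            "timezone-annotated timestamps refused: records must already be "
            "expressed in UTC-6 civil time"
        )
    out = records.copy()
    out["date"] = dates.dt.normalize()
    hours = out["hour"].to_numpy()
    if ((hours < 0) | (hours > 23)).any():
        raise ValueError("hour out of range 0-23")
    pm = out["pm25"].to_numpy(float)
    if not np.isfinite(pm).all():
        raise ValueError("non-finite PM2.5 concentration")
    if (pm < 0).any():
        raise ValueError("negative PM2.5 concentration")
    if out.duplicated(subset=["station_id", "date", "hour"]).any():
        raise ValueError("duplicate (station, timestamp) pair: ambiguous observation")
    return out


def aggregate_station_days(
    records: pd.DataFrame, min_hours: int = MIN_HOURS_DEFAULT
) -> pd.DataFrame:
    """Aggregate hourly records into retained station-day mean/max targets.

    Parameters
    ----------
    records
        Columns ``station_id``, ``date``, ``hour`` (0-23, UTC-6), ``pm25``
        (ug/m3).  Duplicate station-hours or negative concentrations are
        hard errors.
    min_hours
        Completeness rule: a station-day is retained only when it has at
        least this many distinct observed hours.

    Returns
    -------
    DataFrame with columns ``station_id``, ``date``, ``mean_pm25``,
    ``max_pm25``, ``n_hours``, one row per retained station-day.
    """
    records = _validate_records(records)
    grouped = records.groupby(["station_id", "date"], sort=True)["pm25"].agg(
        mean_pm25="mean", max_pm25="max", n_hours="count"
    )
    out = grouped.reset_index()
    return out[out["n_hours"] >= min_hours].reset_index(drop=True)


def modal_peak_hour(records: pd.DataFrame, min_hours: int = MIN_HOURS_DEFAULT) -> int:
    """Most frequent within-day peak hour across retained station-days.

    For every retained station-day the argmax hour of the hourly series is
    taken (earliest hour on exact value ties); the mode of those argmax
    hours is returned, again breaking ties toward the earlier hour.
    """
    records = _validate_records(records)
    peaks = []
    for _, grp in records.groupby(["station_id", "date"], sort=True):
        if grp["hour"].nunique() < min_hours:
            continue
        grp = grp.sort_values("hour")
        peaks.append(int(grp["hour"].iloc[int(np.argmax(grp["pm25"].to_numpy()))]))
    if not peaks:
        raise ValueError("no retained station-days")
    counts = pd.Series(peaks).value_counts()
    top = counts[counts == counts.max()]
    return int(min(top.index))
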