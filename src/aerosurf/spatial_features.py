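"""Feature rows for station-days (training) and cell-days (prediction).

Each row carries exactly 14 predictors in a frozen column order: projected
coordinates, an integer date index, the same-day inverse-distance-weighted
(IDW) interpolation of the dependent variable, two satellite AOD layers,
a modeled surface-PM layer, temperature (mean of the daily max and min
layers), precipitation, vapor pressure, boundary-layer height, two wind
components, and static road density.  For the daily-max target the
sub-daily fields (modeled PM, boundary layer, winds) enter as their
mid-morning values instead of daily means.

Training rows at a station always exclude that station's own observation
from their IDW sources; this is what makes the residual target honest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Frozen predictor column order (exactly 14 slots).
FEATURE_COLUMNS = (
    "x",
    "y",
    "date_index",
    "idw_baseline",
    "aod_terra",
    "aod_aqua",
    "modeled_pm",
    "temperature",
    "precipitation",
    "vapor_pressure",
    "pbl_height",
    "wind_u",
    "wind_v",
    "road_density",
)

META_COLUMNS = ("unit_id", "date", "cell_id", "target_kind")

#: Sub-daily fields that switch to their mid-morning value for the max target.
_SUBDAILY = ("modeled_pm", "pbl_height", "wind_u", "wind_v")

COINCIDENT_EPS = 1.0  # meters

TARGET_VALUE_COLUMN = {"daily_mean": "mean_pm25", "daily_max": "max_pm25"}


def idw_interpolate(
    targets: np.ndarray,
    sources: np.ndarray,
    values: np.ndarray,
    exponent: float = 2.0,
    eps: float = COINCIDENT_EPS,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation on planar coordinates.

    ``targets`` is (m, 2) and ``sources`` (n, 2) in projected meters.  Each
    target gets sum(w_i v_i)/sum(w_i) with w_i = d_i^-exponent; a target
    within ``eps`` of a source returns that source's value exactly.  The
    output is a convex combination of source values.
    """
    targets = np.atleast_2d(np.asarray(targets, float))
    sources = np.atleast_2d(np.asarray(sources, float))
    values = np.asarray(values, float)
    if sources.shape[0] == 0:
        raise ValueError("no same-day source observations")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    d = cdist(targets, sources)
    out = np.empty(len(targets))
    near = d < eps
    has_near = near.any(axis=1)
    if has_near.any():
        out[has_near] = values[np.argmax(near[has_near], axis=1)]
    far = ~has_near
    if far.any():
        w = d[far] ** (-exponent)
        out[far] = (w @ values) / w.sum(axis=1)
    return out


def _sources_by_date(station_days: pd.DataFrame, stations: pd.DataFrame, value_col: str):
    """date -> (station ids, coords, values) of same-day observations."""
    merged = station_days.merge(
        stations[["station_id", "x", "y"]], on="station_id", validate="many_to_one"
    )
    out = {}
    for date, grp in merged.groupby("date", sort=True):
        out[date] = (
            grp["station_id"].to_numpy(),
            grp[["x", "y"]].to_numpy(float),
            grp[value_col].to_numpy(float),
        )
    return out


def build_features(
    units: pd.DataFrame,
    predictors,
    target_kind: str,
    same_day_sources: pd.DataFrame,
    stations: pd.DataFrame,
    exclude_own_station: bool = False,
    exponent: float = 2.0,
    date_origin=None,
) -> pd.DataFrame:
    """Assemble the 14-predictor feature table for unit-days.

    Parameters
    ----------
    units
        One row per requested unit-day: ``unit_id``, ``x``, ``y``,
        ``cell_id``, ``date``.  For training rows ``unit_id`` is the
        station id; for prediction rows it is the cell id.
    predictors
        A :class:`~aerosurf.synthetic_data.PredictorFields` (or anything
        with the same daily/at_hour/static layout).
    target_kind
        ``daily_mean`` or ``daily_max``; selects the IDW source column and
        the temporal aggregation of the sub-daily fields.
    same_day_sources
        Station-day table supplying IDW source values of the matching
        target kind.
    exclude_own_station
        When true, a row whose ``unit_id`` matches a source station id has
        that station removed from its own IDW sources (training rows).

    Rows whose day has no usable IDW source are dropped and logged.
    """
    if target_kind not in TARGET_VALUE_COLUMN:
        raise ValueError(f"unknown target_kind {target_kind!r}")
    value_col = TARGET_VALUE_COLUMN[target_kind]
    if value_col not in same_day_sources.columns:
        raise ValueError(
            f"sources lack column {value_col!r} required for target {target_kind!r}"
        )

    units = units.reset_index(drop=True).copy()
    units["date"] = pd.to_datetime(units["date"])
    dates_index = pd.DatetimeIndex(predictors.dates)
    date_origin = dates_index.min() if date_origin is None else pd.Timestamp(date_origin)
    day_pos = pd.Series(np.arange(len(dates_index)), index=dates_index)
    cell_pos = pd.Series(
        np.arange(len(predictors.cell_ids)), index=predictors.cell_ids
    )
    if not units["date"].isin(day_pos.index).all():
        raise ValueError("predictor rasters do not cover every requested day")
    if not units["cell_id"].isin(cell_pos.index).all():
        raise ValueError("predictor rasters do not cover every requested cell")
    di = day_pos[units["date"]].to_numpy()
    ci = cell_pos[units["cell_id"]].to_numpy()

    def dyn(name: str) -> np.ndarray:
        if target_kind == "daily_max" and name in _SUBDAILY:
            return predictors.at_hour[name][di, ci]
        return predictors.daily[name][di, ci]

    sources = _sources_by_date(same_day_sources, stations, value_col)
    idw = np.full(len(units), np.nan)
    xy = units[["x", "y"]].to_numpy(float)
    unit_ids = units["unit_id"].to_numpy()
    for date, rows in units.groupby("date").groups.items():
        if date not in sources:
            continue
        sid, sxy, sval = sources[date]
        rows = np.asarray(rows)
        if exclude_own_station:
            for r in rows:
                keep = sid != unit_ids[r]
                if keep.any():
                    idw[r] = idw_interpolate(
                        xy[r : r + 1], sxy[keep], sval[keep], exponent
                    )[0]
        else:
            idw[rows] = idw_interpolate(xy[rows], sxy, sval, exponent)

    features = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "date": units["date"].to_numpy(),
            "cell_id": units["cell_id"].to_numpy(),
            "target_kind": target_kind,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "date_index": (units["date"] - date_origin).dt.days.to_numpy(float),
            "idw_baseline": idw,
            "aod_terra": dyn("aod_terra"),
            "aod_aqua": dyn("aod_aqua"),
            "modeled_pm": dyn("modeled_pm"),
            "temperature": (dyn("temp_max") + dyn("temp_min")) / 2.0,
            "precipitation": dyn("precipitation"),
            "vapor_pressure": dyn("vapor_pressure"),
            "pbl_height": dyn("pbl_height"),
            "wind_u": dyn("wind_u"),
            "wind_v": dyn("wind_v"),
            "road_density": predictors.static["road_density"][ci],
        }
    )
    n_dropped = int(features["idw_baseline"].isna().sum())
    if n_dropped:
        logger.warning(
            "dropping %d unit-day rows with no same-day IDW source observations",
            n_dropped,
        )
        features = features[features["idw_baseline"].notna()]
    return features.reset_index(drop=True)


def cell_units(cells: pd.DataFrame, dates) -> pd.DataFrame:
    """Cartesian unit-day table for prediction over grid cells."""
    dates = pd.DatetimeIndex(dates)
    n_c, n_d = len(cells), len(dates)
    return pd.DataFrame(
        {
            "unit_id": np.repeat(cells["cell_id"].to_numpy(), n_d),
            "x": np.repeat(cells["x"].to_numpy(), n_d),
            "y": np.repeat(cells["y"].to_numpy(), n_d),
            "cell_id": np.repeat(cells["cell_id"].to_numpy(), n_d),
            "date": np.tile(dates.to_numpy(), n_c),
        }
    )


def station_units(station_days: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Unit-day table for training rows: one row per retained station-day."""
    merged = station_days.merge(
        stations[["station_id", "x", "y", "cell_id"]],
        on="station_id",
        validate="many_to_one",
    )
    return pd.DataFrame(
        {
            "unit_id": merged["station_id"].to_numpy(),
            "x": merged["x"].to_numpy(float),
            "y": merged["y"].to_numpy(float),
            "cell_id": merged["cell_id"].to_numpy(),
            "date": merged["date"].to_numpy(),
        }
    )
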