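"""Plain-text readers and writers for the pipeline's tables.

Stations and hourly records travel as CSV; predictor fields and the
population raster as long CSV (cell/raster id, date, variable, value);
polygons as GeoJSON with a ``marginalization`` property.  All writers are
deterministic: fixed column order, fixed float formatting.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

RECORD_COLUMNS = ["station_id", "date", "hour", "pm25"]
STATION_DAY_COLUMNS = ["station_id", "date", "mean_pm25", "max_pm25", "n_hours"]
FLOAT_FORMAT = "%.10g"


def write_records_csv(records: pd.DataFrame, path) -> None:
    out = records[RECORD_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_station_days_csv(station_days: pd.DataFrame, path) -> None:
    out = station_days[STATION_DAY_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_stations_csv(stations: pd.DataFrame, path) -> None:
    stations[["station_id", "x", "y", "cell_id"]].to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_predictors_csv(predictors, path) -> None:
    """Long-format dump: cell_id, date, variable, value (static vars dateless)."""
    frames = []
    dates = pd.DatetimeIndex(predictors.dates).strftime("%Y-%m-%d")
    for group, layers in (("daily", predictors.daily), ("at_hour", predictors.at_hour)):
        for name, arr in sorted(layers.items()):
            n_days, n_cells = arr.shape
            frames.append(pd.DataFrame({
                "cell_id": np.tile(predictors.cell_ids, n_days),
                "date": np.repeat(dates, n_cells),
                "variable": f"{name}@h" if group == "at_hour" else name,
                "value": arr.ravel(),
            }))
    for name, arr in sorted(predictors.static.items()):
        frames.append(pd.DataFrame({
            "cell_id": predictors.cell_ids, "date": "", "variable": name,
            "value": arr,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_population_csv(raster, path) -> None:
    ny, nx = raster.density.shape
    iy, ix = np.divmod(np.arange(raster.density.size), nx)
    pd.DataFrame({
        "row": iy, "col": ix,
        "x0": raster.x0 + ix * raster.dx, "y0": raster.y0 + iy * raster.dy,
        "dx": raster.dx, "dy": raster.dy,
        "density": raster.density.ravel(),
    }).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_polygons_geojson(polygons: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": shapely.geometry.mapping(row["geometry"]),
            "properties": {
                "unit_id": row["unit_id"],
                "marginalization": row["marginalization"],
            },
        }
        for _, row in polygons.iterrows()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  sort_keys=True)


def read_polygons_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    rows = [
        {
            "unit_id": f["properties"]["unit_id"],
            "geometry": shapely_shape(f["geometry"]),
            "marginalization": float(f["properties"]["marginalization"]),
        }
        for f in gj["features"]
    ]
    return pd.DataFrame(rows)


def write_metrics_csv(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
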