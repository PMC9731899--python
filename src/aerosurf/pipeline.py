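"""End-to-end orchestration: simulate -> ingest -> features -> tune -> predict.

These helpers wire the modules together the way a study run would: the
synthetic region is generated from one seed, hourly records aggregated to
station-days, two models (daily mean, daily 1-h max) tuned and fit on all
stations, prediction surfaces produced for every cell-day with at least
one same-day observation, and the exposure applications computed on the
daily-mean surface.  :func:`run_pipeline` writes all reports as
deterministic text files, so identical seeds give byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aerosurf import evaluation, exposure_apps, io, residual_model, synthetic_data
from aerosurf.exposure_apps import ExposureSurface, RegulatoryLimits
from aerosurf.spatial_features import (
    TARGET_VALUE_COLUMN,
    build_features,
    cell_units,
    station_units,
)
from aerosurf.station_ingest import aggregate_station_days

logger = logging.getLogger(__name__)


@dataclass
class TargetRun:
    """Fitted model plus its training artifacts for one target kind."""

    target_kind: str
    station_days: pd.DataFrame
    features: pd.DataFrame
    targets: np.ndarray
    model: residual_model.FittedExposureModel


def training_features(dataset, station_days, target_kind, date_origin=None):
    """Training feature rows (own-station excluded from IDW) with targets."""
    value_col = TARGET_VALUE_COLUMN[target_kind]
    stations = dataset.fixture.stations
    feats = build_features(
        station_units(station_days, stations), dataset.predictors, target_kind,
        same_day_sources=station_days, stations=stations,
        exclude_own_station=True, date_origin=date_origin,
    )
    y = feats.merge(
        station_days[["station_id", "date", value_col]],
        left_on=["unit_id", "date"], right_on=["station_id", "date"],
    )[value_col].to_numpy(float)
    return feats, y


def fit_target(dataset, station_days, target_kind, candidates, seed) -> TargetRun:
    """Tune (twofold station-wise CV) and fit the final model on all stations."""
    feats, y = training_features(dataset, station_days, target_kind)
    hp = residual_model.tune(
        feats, y, feats["unit_id"].to_numpy(), candidates, seed=seed
    )
    model = residual_model.fit(feats, y, hp, seed=seed, target_kind=target_kind,
                               allow_zero_trees=True)
    return TargetRun(target_kind=target_kind, station_days=station_days,
                     features=feats, targets=y, model=model)


def predict_surface(dataset, run: TargetRun, idw_only: bool = False) -> ExposureSurface:
    """Per-cell per-day prediction surface for the fitted model.

    Cell-day rows take their IDW baseline from all same-day station
    observations.  Days without any observation have no defined baseline;
    they are dropped from the surface and logged.  With ``idw_only`` the
    ensemble is skipped and the surface is the bare IDW interpolation.
    """
    cells = dataset.fixture.cells
    feats = build_features(
        cell_units(cells, dataset.predictors.dates), dataset.predictors,
        run.target_kind, same_day_sources=run.station_days,
        stations=dataset.fixture.stations, exclude_own_station=False,
        date_origin=pd.to_datetime(run.station_days["date"]).min(),
    )
    if idw_only:
        pred = feats["idw_baseline"].to_numpy(float)
    else:
        pred = residual_model.predict(run.model, feats)
    wide = (
        pd.DataFrame({"date": feats["date"], "cell_id": feats["cell_id"], "v": pred})
        .pivot(index="date", columns="cell_id", values="v")
        .reindex(columns=cells["cell_id"].to_numpy())
    )
    complete = wide.notna().all(axis=1)
    if not complete.all():
        logger.warning("dropping %d days without complete predictions",
                       int((~complete).sum()))
        wide = wide[complete]
    return ExposureSurface(
        dates=pd.DatetimeIndex(wide.index), cell_ids=cells["cell_id"].to_numpy(),
        values=wide.to_numpy(float), target_kind=run.target_kind,
    )


def subset_predictor_days(arr: np.ndarray, all_dates, surface_dates) -> np.ndarray:
    """Rows of a (day, cell) predictor array matching a surface's dates."""
    pos = pd.Series(np.arange(len(all_dates)), index=pd.DatetimeIndex(all_dates))
    return arr[pos[pd.DatetimeIndex(surface_dates)].to_numpy()]


def run_pipeline(
    config: synthetic_data.SyntheticConfig | None = None,
    seed: int = 1,
    out_dir: str | Path = "aerosurf_out",
    n_candidates: int = 10,
    run_loso: bool = True,
    limits: RegulatoryLimits | None = None,
) -> dict:
    """Full study run on the synthetic region; writes deterministic reports.

    Writes to ``out_dir``: per-target LOSO metric tables by year and
    season (CSV), the compliance and heat-co-occurrence reports (JSON),
    the daily max:mean ratio series (CSV) and the areal-linkage summary
    (CSV).  Returns the in-memory results keyed like the files.
    """
    config = config or synthetic_data.SyntheticConfig(seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    limits = limits or RegulatoryLimits()

    dataset = synthetic_data.generate(config)
    station_days = aggregate_station_days(dataset.records)
    candidates = residual_model.sample_hyperparameters(n_candidates, seed=seed)
    results: dict = {"dataset": dataset, "station_days": station_days}

    runs = {}
    for target_kind in ("daily_mean", "daily_max"):
        short = "mean" if target_kind == "daily_mean" else "max"
        if run_loso:
            folds = evaluation.loso_cv(
                station_days, dataset.predictors, candidates, seed=seed,
                stations=dataset.fixture.stations, target_kind=target_kind,
            )
            for by in ("year", "season"):
                metrics = evaluation.stratify(folds, by=by)
                io.write_metrics_csv(metrics, out_dir / f"metrics_{short}_{by}.csv")
                results[f"metrics_{short}_{by}"] = metrics
            results[f"folds_{short}"] = folds
        runs[target_kind] = fit_target(dataset, station_days, target_kind,
                                       candidates, seed=seed)

    mean_surface = predict_surface(dataset, runs["daily_mean"])
    max_surface = predict_surface(dataset, runs["daily_max"])
    idw_surface = predict_surface(dataset, runs["daily_mean"], idw_only=True)
    results.update(mean_surface=mean_surface, max_surface=max_surface,
                   idw_surface=idw_surface, runs=runs)

    year = int(mean_surface.dates.year.min())
    populations = exposure_apps.populate_cells(
        dataset.fixture.cells, dataset.fixture.cell_size, dataset.fixture.population
    )
    compliance = exposure_apps.compliance_report(
        mean_surface, populations, limits, year=year,
        comparison_surface=idw_surface,
    )
    io.write_json_report(compliance, out_dir / "compliance.json")

    precip = subset_predictor_days(
        dataset.predictors.daily["precipitation"], dataset.predictors.dates,
        mean_surface.dates,
    )
    common = mean_surface.dates.intersection(max_surface.dates)
    ratio = exposure_apps.daily_ratio_series(
        _align(mean_surface, common), _align(max_surface, common),
        subset_predictor_days(dataset.predictors.daily["precipitation"],
                              dataset.predictors.dates, common),
    )
    ratio["series"].assign(
        date=ratio["series"]["date"].dt.strftime("%Y-%m-%d")
    ).to_csv(out_dir / "daily_ratio.csv", index=False, float_format="%.10g")

    temp_c = subset_predictor_days(
        synthetic_data.temperature_celsius(dataset.predictors),
        dataset.predictors.dates, mean_surface.dates,
    )
    heat = exposure_apps.heat_cooccurrence(mean_surface, temp_c, limits)
    io.write_json_report(
        {k: v for k, v in heat.items() if k != "conditional_quartiles"},
        out_dir / "heat.json",
    )
    heat["conditional_quartiles"].to_csv(
        out_dir / "heat_conditional_quartiles.csv", index=False, float_format="%.10g"
    )

    areal = exposure_apps.areal_link(
        mean_surface, dataset.fixture.polygons, dataset.fixture.cells, year
    )
    areal["per_polygon"].to_csv(out_dir / "areal_per_polygon.csv", index=False,
                                float_format="%.10g")
    areal["by_bin"].to_csv(out_dir / "areal_by_bin.csv", index=False,
                           float_format="%.10g")

    results.update(populations=populations, compliance=compliance, ratio=ratio,
                   heat=heat, areal=areal, precipitation=precip, year=year)
    return results


def _align(surface: ExposureSurface, dates) -> ExposureSurface:
    keep = surface.dates.isin(dates)
    return ExposureSurface(surface.dates[keep], surface.cell_ids,
                           surface.values[keep], surface.target_kind)
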