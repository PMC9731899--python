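"""Leave-one-station-out cross-validation and absolute-loss-first metrics.

Each monitoring station is held out in turn; the model (including its
nested twofold tuning CV) sees only the remaining stations, and every IDW
baseline inside the fold — for training rows and held-out rows alike — is
recomputed from the source set minus the held-out station, so none of the
held-out station's observations can leak into its own predictions.

Models are judged under absolute loss: mean absolute error (MAE) against
the mean absolute deviation from the median (MAD) as the baseline spread;
R^2 = 1 - MSE/variance, RMSE and SD are reported for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from aerosurf import residual_model
from aerosurf.spatial_features import TARGET_VALUE_COLUMN, build_features, station_units
from aerosurf.station_ingest import season_of_dates

METRIC_COLUMNS = ("stratum", "n_stations", "n_obs", "R2", "SD", "RMSE", "MAD", "MAE")


@dataclass
class MetricsRow:
    """Absolute-loss-first accuracy summary for one stratum."""

    stratum: str
    n_stations: int
    n_obs: int
    R2: float
    SD: float
    RMSE: float
    MAD: float
    MAE: float


@dataclass
class CVFoldResult:
    """Held-out predictions for one station fold."""

    held_out_station: str
    rows: pd.DataFrame  # date, observed, predicted
    hp: residual_model.Hyperparameters


def compute_metrics(observed, predicted, stratum: str = "overall",
                    n_stations: int = 0) -> MetricsRow:
    """MAE, MAD, RMSE, SD and R^2 = 1 - MSE/var for paired vectors.

    Variance and SD use the population (divide-by-n) convention; MAD is
    the mean absolute deviation of the observations from their median.
    Zero observed variance makes R^2 undefined (NaN).
    """
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if o.shape != p.shape or o.size == 0:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    if not (np.isfinite(o).all() and np.isfinite(p).all()):
        raise ValueError("non-finite values")
    err = o - p
    mse = float(np.mean(err**2))
    var = float(np.var(o))
    return MetricsRow(
        stratum=stratum,
        n_stations=n_stations,
        n_obs=o.size,
        R2=(1.0 - mse / var) if var > 0 else float("nan"),
        SD=float(np.sqrt(var)),
        RMSE=float(np.sqrt(mse)),
        MAD=float(np.mean(np.abs(o - np.median(o)))),
        MAE=float(np.mean(np.abs(err))),
    )


def build_fold_features(
    station_days: pd.DataFrame,
    predictors,
    stations: pd.DataFrame,
    held_out_station: str,
    target_kind: str,
    date_origin=None,
    leak_holdout: bool = False,
):
    """Training and test feature tables (plus targets) for one LOSO fold.

    The IDW source set is the station-day table minus the held-out station
    for *both* sides; training rows additionally exclude their own station.
    ``leak_holdout`` deliberately keeps the held-out station among the
    training-side IDW sources — a leaky variant that exists only so tests
    can prove the guard detects it.  Never enable it in analysis.
    """
    value_col = TARGET_VALUE_COLUMN[target_kind]
    is_out = station_days["station_id"] == held_out_station
    train_days = station_days[~is_out].reset_index(drop=True)
    test_days = station_days[is_out].reset_index(drop=True)
    if train_days["station_id"].nunique() < 2:
        raise ValueError("fewer than 2 training stations in fold")

    train_sources = station_days if leak_holdout else train_days
    f_train = build_features(
        station_units(train_days, stations), predictors, target_kind,
        same_day_sources=train_sources, stations=stations,
        exclude_own_station=True, date_origin=date_origin,
    )
    f_test = build_features(
        station_units(test_days, stations), predictors, target_kind,
        same_day_sources=train_days, stations=stations,
        exclude_own_station=False, date_origin=date_origin,
    )
    key = ["station_id", "date"]
    y_train = f_train.merge(
        train_days[key + [value_col]], left_on=["unit_id", "date"], right_on=key
    )[value_col].to_numpy(float)
    y_test = f_test.merge(
        test_days[key + [value_col]], left_on=["unit_id", "date"], right_on=key
    )[value_col].to_numpy(float)
    return f_train, y_train, f_test, y_test


def loso_cv(
    station_days: pd.DataFrame,
    predictors,
    candidates: list,
    seed: int = 0,
    stations: pd.DataFrame = None,
    target_kind: str = "daily_mean",
) -> list:
    """One fold per station; nested tuning on training stations only.

    Returns a list of :class:`CVFoldResult` whose test rows together cover
    every retained station-day exactly once.
    """
    if stations is None:
        raise ValueError("stations table with coordinates is required")
    ids = np.sort(station_days["station_id"].unique())
    if len(ids) < 3:
        raise ValueError("LOSO needs at least 3 stations")
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=len(ids))
    date_origin = pd.to_datetime(station_days["date"]).min()

    results = []
    for fold_seed, held_out in zip(fold_seeds, ids):
        f_tr, y_tr, f_te, y_te = build_fold_features(
            station_days, predictors, stations, held_out, target_kind,
            date_origin=date_origin,
        )
        hp = residual_model.tune(
            f_tr, y_tr, f_tr["unit_id"].to_numpy(), candidates, seed=int(fold_seed)
        )
        model = residual_model.fit(f_tr, y_tr, hp, seed=int(fold_seed),
                                   target_kind=target_kind, allow_zero_trees=True)
        pred = residual_model.predict(model, f_te)
        results.append(
            CVFoldResult(
                held_out_station=str(held_out),
                rows=pd.DataFrame(
                    {"date": f_te["date"], "observed": y_te, "predicted": pred}
                ),
                hp=hp,
            )
        )
    return results


def _pooled(results) -> pd.DataFrame:
    frames = []
    for r in results:
        d = r.rows.copy()
        d["station_id"] = r.held_out_station
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def stratify(results: list, by: str = "year") -> pd.DataFrame:
    """Metric rows overall and per stratum (calendar year or season).

    Seasonal strata pool across years.  Within-stratum R^2 uses that
    stratum's own observed variance.
    """
    if by not in ("year", "season"):
        raise ValueError("by must be 'year' or 'season'")
    pooled = _pooled(results)
    if pooled.empty:
        raise ValueError("no CV results")
    dates = pd.to_datetime(pooled["date"])
    key = dates.dt.year.astype(str) if by == "year" else pd.Series(
        season_of_dates(dates), index=pooled.index
    )
    rows = [
        compute_metrics(pooled["observed"], pooled["predicted"], "overall",
                        pooled["station_id"].nunique())
    ]
    for label, grp in pooled.groupby(key, sort=True):
        rows.append(
            compute_metrics(grp["observed"], grp["predicted"], str(label),
                            grp["station_id"].nunique())
        )
    return pd.DataFrame([r.__dict__ for r in rows], columns=METRIC_COLUMNS)
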