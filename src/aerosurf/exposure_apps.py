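"""Exposure applications on prediction surfaces.

Three applications of the per-cell per-day prediction surfaces, mirroring
what an air-quality authority would ask of them:

* regulatory compliance — "yearly" concentration means computed as the
  mean of four 3-month (calendar-quarter) means per the Mexican standard,
  person-days of daily-limit exceedance using area-weighted population,
  and population-weighted exposure ECDFs;
* co-occurrence of high PM2.5 with heat — rank correlation and
  conditional summaries of PM against daily-mean temperature;
* areal deprivation linkage — polygon units scored by a marginalization
  index receive the mean prediction of the grid cells whose centroids
  fall inside them.

The default limits are the Mexican ambient standards: 10 ug/m3 annual
and 41 ug/m3 daily mean; "exceeds" means strictly worse than the limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from aerosurf.station_ingest import season_of_dates

logger = logging.getLogger(__name__)

ANNUAL_LIMIT = 10.0  # ug/m3
DAILY_LIMIT = 41.0   # ug/m3


@dataclass
class RegulatoryLimits:
    annual_limit: float = ANNUAL_LIMIT
    daily_limit: float = DAILY_LIMIT

    def __post_init__(self):
        if self.annual_limit <= 0 or self.daily_limit <= 0:
            raise ValueError("limits must be positive")


@dataclass
class ExposureSurface:
    """Per-cell per-day predicted concentrations for one target kind."""

    dates: pd.DatetimeIndex
    cell_ids: np.ndarray
    values: np.ndarray  # (n_days, n_cells), ug/m3
    target_kind: str = "daily_mean"

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.dates), len(self.cell_ids)):
            raise ValueError("surface shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("surface contains non-finite values")

    def year_slice(self, year: int) -> "ExposureSurface":
        keep = self.dates.year == year
        if not keep.any():
            raise ValueError(f"surface has no days in {year}")
        return ExposureSurface(self.dates[keep], self.cell_ids,
                               self.values[keep], self.target_kind)


# ---------------------------------------------------------------------------
# regulatory annual mean

def regulatory_annual_mean(dates, values) -> float:
    """Yearly mean as the mean of four calendar-quarter means.

    Each quarterly mean is the mean of that quarter's daily values; the
    four quarterly means are averaged with equal weight regardless of
    quarter lengths.  Any empty quarter makes the result missing (NaN).
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, float)
    if len(set(dates.year)) != 1:
        raise ValueError("series must cover a single calendar year")
    quarters = (dates.month - 1) // 3
    qmeans = []
    for q in range(4):
        sel = quarters == q
        if not sel.any():
            logger.warning("empty quarter %d: annual mean reported missing", q + 1)
            return float("nan")
        qmeans.append(values[sel].mean())
    return float(np.mean(qmeans))


def annual_mean_surface(surface: ExposureSurface, year: int) -> np.ndarray:
    """Regulatory annual mean per cell for one year (vector over cells)."""
    s = surface.year_slice(year)
    quarters = (s.dates.month - 1) // 3
    qmeans = np.empty((4, len(s.cell_ids)))
    for q in range(4):
        sel = quarters == q
        if not sel.any():
            return np.full(len(s.cell_ids), np.nan)
        qmeans[q] = s.values[sel].mean(axis=0)
    return qmeans.mean(axis=0)


# ---------------------------------------------------------------------------
# population

def populate_cells(cells: pd.DataFrame, cell_size: float, raster) -> pd.DataFrame:
    """Per-cell population from an offset density raster.

    Each model cell's density is the area-weighted mean of the densities
    of the intersecting raster cells (axis-aligned interval overlap, exact
    arithmetic); persons = density (per km2) x cell area (km2).  A model
    cell not fully covered by the raster is a hard error.
    """
    xe, ye = raster.x_edges, raster.y_edges
    dens = raster.density
    half = cell_size / 2.0
    out = np.empty(len(cells))
    for i, (cx, cy) in enumerate(zip(cells["x"].to_numpy(), cells["y"].to_numpy())):
        x0, x1, y0, y1 = cx - half, cx + half, cy - half, cy + half
        if x0 < xe[0] - 1e-9 or x1 > xe[-1] + 1e-9 or y0 < ye[0] - 1e-9 or y1 > ye[-1] + 1e-9:
            raise ValueError(f"population raster gap under cell {cells['cell_id'].iloc[i]}")
        ix = np.nonzero((xe[:-1] < x1) & (xe[1:] > x0))[0]
        iy = np.nonzero((ye[:-1] < y1) & (ye[1:] > y0))[0]
        wx = np.minimum(xe[ix + 1], x1) - np.maximum(xe[ix], x0)
        wy = np.minimum(ye[iy + 1], y1) - np.maximum(ye[iy], y0)
        areas = np.outer(wy, wx)
        out[i] = (dens[np.ix_(iy, ix)] * areas).sum() / areas.sum()
    area_km2 = cell_size**2 / 1e6
    return pd.DataFrame(
        {"cell_id": cells["cell_id"].to_numpy(), "density": out,
         "persons": out * area_km2}
    )


# ---------------------------------------------------------------------------
# compliance

def _person_days(surface: ExposureSurface, persons: np.ndarray, daily_limit: float):
    exceed = surface.values > daily_limit        # (n_days, n_cells)
    days_per_cell = exceed.sum(axis=0).astype(float)
    total_person_days = float(persons @ days_per_cell)
    return days_per_cell, total_person_days


def compliance_report(
    surface: ExposureSurface,
    populations: pd.DataFrame,
    limits: RegulatoryLimits = None,
    year: int | None = None,
    comparison_surface: ExposureSurface | None = None,
) -> dict:
    """Population exposure relative to the annual and daily limits.

    Returns per-surface summaries: persons (count and fraction) whose
    regulatory annual mean is worse than the annual limit and worse than
    twice it; the population-weighted (and unweighted) mean number of
    exceedance days per person; and total person-days of exceedance.
    An optional comparison surface (typically IDW-only) is summarized the
    same way under the key ``"comparison"``.
    """
    limits = limits or RegulatoryLimits()
    if surface.target_kind != "daily_mean":
        raise ValueError("compliance is defined on the daily-mean surface")
    year = int(surface.dates.year.min()) if year is None else year
    pop = populations.set_index("cell_id").loc[surface.cell_ids, "persons"].to_numpy()

    def summarize(s: ExposureSurface) -> dict:
        s = s.year_slice(year)
        annual = annual_mean_surface(s, year)
        total_pop = pop.sum()
        over = annual > limits.annual_limit
        over2 = annual > 2 * limits.annual_limit
        days_per_cell, person_days = _person_days(s, pop, limits.daily_limit)
        return {
            "persons_above_annual": float(pop[over].sum()),
            "frac_above_annual": float(pop[over].sum() / total_pop),
            "frac_above_twice_annual": float(pop[over2].sum() / total_pop),
            "mean_exceedance_days_weighted": float(pop @ days_per_cell / total_pop),
            "mean_exceedance_days_unweighted": float(days_per_cell.mean()),
            "person_days_exceedance": person_days,
        }

    report = {"year": year, "limits": {"annual": limits.annual_limit,
                                       "daily": limits.daily_limit},
              "model": summarize(surface)}
    if comparison_surface is not None:
        report["comparison"] = summarize(comparison_surface)
    return report


def population_ecdf(surface: ExposureSurface, populations: pd.DataFrame,
                    year: int) -> pd.DataFrame:
    """Population-weighted ECDF of per-cell regulatory annual means.

    Returns a step function as a DataFrame (``concentration`` sorted
    ascending, ``cum_frac`` nondecreasing 0 -> 1).  Quantiles come from
    :func:`weighted_quantile`.
    """
    annual = annual_mean_surface(surface, year)
    pop = populations.set_index("cell_id").loc[surface.cell_ids, "persons"].to_numpy()
    ok = np.isfinite(annual)
    order = np.argsort(annual[ok], kind="stable")
    v = annual[ok][order]
    w = pop[ok][order]
    cum = np.cumsum(w) / w.sum()
    return pd.DataFrame({"concentration": v, "cum_frac": cum})


def weighted_quantile(ecdf: pd.DataFrame, q: float) -> float:
    """Smallest concentration whose cumulative population fraction >= q."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    idx = np.searchsorted(ecdf["cum_frac"].to_numpy(), q, side="left")
    idx = min(idx, len(ecdf) - 1)
    return float(ecdf["concentration"].iloc[idx])


# ---------------------------------------------------------------------------
# max:mean daily ratio

def daily_ratio_series(
    mean_surface: ExposureSurface,
    max_surface: ExposureSurface,
    precipitation: np.ndarray,
    rain_threshold: float = 1.0,
    per_cell_ratio: bool = False,
) -> dict:
    """Per-day max:mean ratio, split by rainy vs dry days.

    The default collapses across cells first (ratio of spatial means);
    ``per_cell_ratio`` instead averages the per-cell ratios.  A day is
    rainy when its mean per-cell precipitation is at least the threshold.
    Days with a zero spatial mean are excluded and logged.
    """
    if not mean_surface.dates.equals(max_surface.dates) or not np.array_equal(
        mean_surface.cell_ids, max_surface.cell_ids
    ):
        raise ValueError("surfaces not aligned on cells and dates")
    mean_over_cells = mean_surface.values.mean(axis=1)
    ok = mean_over_cells > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("excluding %d days with zero spatial mean", n_bad)
    if per_cell_ratio:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.nanmean(max_surface.values / mean_surface.values, axis=1)
    else:
        ratio = np.divide(max_surface.values.mean(axis=1), mean_over_cells,
                          out=np.full(len(mean_over_cells), np.nan), where=ok)
    rainy = np.asarray(precipitation, float).mean(axis=1) >= rain_threshold
    series = pd.DataFrame(
        {"date": mean_surface.dates, "ratio": ratio, "rainy": rainy}
    )[ok]
    return {
        "series": series,
        "mean_ratio_dry": float(series.loc[~series["rainy"], "ratio"].mean()),
        "mean_ratio_rainy": float(series.loc[series["rainy"], "ratio"].mean()),
    }


# ---------------------------------------------------------------------------
# heat co-occurrence

def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall rank correlation (tau-b).

    Undefined (NaN) when either vector is entirely tied.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def heat_cooccurrence(
    pm_surface: ExposureSurface,
    temperature: np.ndarray,
    limits: RegulatoryLimits = None,
    temp_threshold: float = 20.0,
) -> dict:
    """Joint behavior of daily-mean PM2.5 and daily-mean temperature (degC).

    Reports the overall Kendall tau over cell-days; per-season PM
    quartiles conditional on temperature rounded to 0.1 degC; the median
    temperature on PM-exceedance cell-days versus all others; and the
    median PM on cell-days at or above the temperature threshold versus
    cooler ones.
    """
    limits = limits or RegulatoryLimits()
    temp = np.asarray(temperature, float)
    if temp.shape != pm_surface.values.shape:
        raise ValueError("temperature surface not aligned with PM surface")
    pm = pm_surface.values.ravel()
    t = temp.ravel()
    season = np.repeat(season_of_dates(pm_surface.dates), len(pm_surface.cell_ids))

    cond = (
        pd.DataFrame({"season": season, "temp_bin": np.round(t, 1), "pm": pm})
        .groupby(["season", "temp_bin"])["pm"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q25", 0.5: "q50", 0.75: "q75"})
        .reset_index()
    )

    exceed = pm > limits.daily_limit
    hot = t >= temp_threshold
    return {
        "tau": kendall_tau(pm, t),
        "conditional_quartiles": cond,
        "n_exceedance_cell_days": int(exceed.sum()),
        "n_cell_days": int(pm.size),
        "median_temp_exceedance": float(np.median(t[exceed])) if exceed.any() else float("nan"),
        "median_temp_other": float(np.median(t[~exceed])) if (~exceed).any() else float("nan"),
        "n_hot_cell_days": int(hot.sum()),
        "median_pm_hot": float(np.median(pm[hot])) if hot.any() else float("nan"),
        "median_pm_other": float(np.median(pm[~hot])) if (~hot).any() else float("nan"),
    }


# ---------------------------------------------------------------------------
# areal deprivation linkage

def areal_link(
    surface: ExposureSurface,
    polygons: pd.DataFrame,
    cells: pd.DataFrame,
    year: int,
    bin_width: float = 0.5,
) -> dict:
    """Polygon-level exposure and its relation to a marginalization score.

    Each polygon receives the unweighted mean of the annual-mean
    predictions of cells whose centroids fall inside it (boundary points
    count as inside).  Polygons containing no centroid are missing and
    excluded from the correlation.  Scores are also grouped into
    ``bin_width``-unit bins aligned at 0 for per-group mean exposure.
    """
    annual = pd.Series(annual_mean_surface(surface, year), index=surface.cell_ids)
    pts = shapely.points(cells["x"].to_numpy(), cells["y"].to_numpy())
    values, scores, ids = [], [], []
    for _, row in polygons.iterrows():
        inside = shapely.covers(row["geometry"], pts)
        ids.append(row["unit_id"])
        scores.append(float(row["marginalization"]))
        if inside.any():
            values.append(float(annual.loc[cells["cell_id"].to_numpy()[inside]].mean()))
        else:
            values.append(float("nan"))
    per_polygon = pd.DataFrame(
        {"unit_id": ids, "marginalization": scores, "exposure": values}
    )
    ok = per_polygon["exposure"].notna()
    tau = (
        kendall_tau(per_polygon.loc[ok, "marginalization"],
                    per_polygon.loc[ok, "exposure"])
        if ok.sum() >= 2 else float("nan")
    )
    binned = per_polygon[ok].copy()
    binned["bin_lo"] = np.floor(binned["marginalization"] / bin_width) * bin_width
    groups = (
        binned.groupby("bin_lo")["exposure"].agg(["mean", "count"]).reset_index()
        .rename(columns={"mean": "mean_exposure", "count": "n_polygons"})
    )
    return {"per_polygon": per_polygon, "tau": tau, "by_bin": groups}
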