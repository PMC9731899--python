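"""Self-contained toy study region with the structure the analysis assumes.

The generator emulates, at CI scale, a sparsely monitored metropolitan
airshed on a high plateau: a square planar grid of ~1 km cells restricted
to the largest connected low-elevation component, a handful of monitoring
stations, hourly PM2.5 with a mid-morning peak and lognormal noise, two
dry seasons and one rainy season, spatially smooth gridded predictors
correlated with the latent truth, a population-density raster deliberately
misaligned with the model grid, and scored polygons standing in for census
units.  Everything is reproducible from a single integer seed.

Coordinates are plain projected meters; no geodesy is involved.  The
latent spatial fields are Gaussian-filtered white noise (a smooth
GP-style surrogate); their correlation length is a config knob, not a
claim about real aerosol fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from shapely.geometry import box

from aerosurf.station_ingest import season_of_dates

DEFAULT_PEAK_HOUR = 10
DEFAULT_CELL_SIZE = 927.0  # meters


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.  Defaults give a minutes-scale fixture."""

    nx: int = 20
    ny: int = 20
    cell_size: float = DEFAULT_CELL_SIZE
    n_stations: int = 8
    n_polygons: int = 6
    start_date: str = "2018-01-01"
    n_years: int = 2
    elevation_ceiling: float = 3000.0  # meters above sea level
    base_elevation: float = 2250.0
    peak_hour: int = DEFAULT_PEAK_HOUR
    peak_amplitude: float = 1.8        # height of the diurnal bump over the flat level
    profile_jitter: float = 0.05       # day-to-day perturbation of the hourly profile
    base_pm: float = 22.0              # ug/m3, regional log-scale median
    season_log_effect: dict = field(
        default_factory=lambda: {"cold_dry": 0.25, "warm_dry": 0.10, "rainy": -0.25}
    )
    spatial_sd: float = 0.30           # log-scale sd of the static spatial pattern
    spatial_corr_cells: float = 3.0    # Gaussian correlation length, in cells
    daily_sd: float = 0.25             # region-wide day-to-day log fluctuation
    synoptic_sd: float = 0.20          # day-varying smooth spatial anomaly (weather)
    synoptic_corr_cells: float = 4.0   # its correlation length, in cells
    cellday_sd: float = 0.08           # residual unstructured cell-day log noise
    noise_sigma: float = 0.3           # lognormal station measurement noise
    missingness: float = 0.1           # hourly record drop rate
    informativeness: float = 0.8       # predictor-truth blend weight in [0, 1]
    temp_pm_coupling: float = 0.5      # degC shift per sd of log PM anomaly
    rain_wet_prob: float = 0.6         # chance a rainy-season day has any rain
    rain_mean_mm: float = 4.0
    aod_gap_day_prob: float = 0.5      # chance a day has satellite coverage gaps
    aod_gap_max_frac: float = 0.4
    population_total: float = 500_000.0
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PopulationRaster:
    """Axis-aligned density raster (persons/km2) on its own, offset grid."""

    x0: float   # west edge
    y0: float   # south edge
    dx: float
    dy: float
    density: np.ndarray  # (ny, nx), row 0 = southmost

    @property
    def x_edges(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.density.shape[1] + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y0 + self.dy * np.arange(self.density.shape[0] + 1)


@dataclass
class RegionFixture:
    """Grid cells inside the region mask, stations, polygons, population."""

    cells: pd.DataFrame          # cell_id, row, col, x, y, elevation
    cell_size: float
    stations: pd.DataFrame       # station_id, x, y, cell_id
    polygons: pd.DataFrame       # unit_id, geometry (shapely), marginalization
    population: PopulationRaster
    seed: int


@dataclass
class TruthField:
    """Latent daily-mean surface and hourly multiplier profile."""

    dates: pd.DatetimeIndex
    cell_ids: np.ndarray
    mean: np.ndarray             # (n_days, n_cells), ug/m3, strictly positive
    hourly_profile: np.ndarray   # (n_days, 24), unit mean per day
    season: np.ndarray           # (n_days,) labels


@dataclass
class PredictorFields:
    """Gridded predictors per cell-day, plus mid-morning variants."""

    dates: pd.DatetimeIndex
    cell_ids: np.ndarray
    daily: dict                  # name -> (n_days, n_cells)
    at_hour: dict                # name -> (n_days, n_cells), sampled at `hour`
    static: dict                 # name -> (n_cells,)
    hour: int = DEFAULT_PEAK_HOUR


@dataclass
class SyntheticDataset:
    """Bundle of everything one study run needs."""

    config: SyntheticConfig
    fixture: RegionFixture
    truth: TruthField
    records: pd.DataFrame
    predictors: PredictorFields


# ---------------------------------------------------------------------------
# region geometry

def region_mask(elevation_grid: np.ndarray, ceiling: float) -> set:
    """Largest 4-connected component of cells at or below an elevation ceiling.

    Cell ids are ``row * ncols + col`` on the rectangular grid.  Returns an
    empty set when no cell qualifies (a misconfigured fixture).
    """
    elevation_grid = np.asarray(elevation_grid, float)
    if elevation_grid.ndim != 2:
        raise ValueError("elevation grid must be 2-D")
    ok = elevation_grid <= ceiling
    if not ok.any():
        return set()
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # edge adjacency
    labels, n = ndimage.label(ok, structure=structure)
    sizes = ndimage.sum_labels(ok, labels, index=np.arange(1, n + 1))
    best = 1 + int(np.argmax(sizes))
    rows, cols = np.nonzero(labels == best)
    ncols = elevation_grid.shape[1]
    return set((rows * ncols + cols).tolist())


def _smooth_field(rng, shape, corr_cells: float) -> np.ndarray:
    """Unit-variance spatially smooth field on the full rectangular grid."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def make_fixture(config: SyntheticConfig | None = None, seed: int | None = None) -> RegionFixture:
    """Build the study region: masked grid, stations, polygons, population."""
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ny, nx, cs = config.ny, config.nx, config.cell_size

    # Elevation: plateau plus smooth ridges; a few ridge cells top the ceiling
    # so the mask is non-trivial but keeps most of the grid.
    ridges = _smooth_field(rng, (ny, nx), config.spatial_corr_cells)
    elevation = config.base_elevation + 300.0 * ridges**2
    mask_ids = region_mask(elevation, config.elevation_ceiling)
    if not mask_ids:
        raise ValueError("no cell below the elevation ceiling; fixture misconfigured")

    rows, cols = np.divmod(np.array(sorted(mask_ids)), nx)
    cells = pd.DataFrame(
        {
            "cell_id": sorted(mask_ids),
            "row": rows,
            "col": cols,
            "x": (cols + 0.5) * cs,
            "y": (rows + 0.5) * cs,
            "elevation": elevation[rows, cols],
        }
    )

    host = rng.choice(len(cells), size=config.n_stations, replace=False)
    jitter = rng.uniform(-0.3, 0.3, size=(config.n_stations, 2)) * cs
    stations = pd.DataFrame(
        {
            "station_id": [f"S{i:02d}" for i in range(config.n_stations)],
            "x": cells["x"].to_numpy()[host] + jitter[:, 0],
            "y": cells["y"].to_numpy()[host] + jitter[:, 1],
            "cell_id": cells["cell_id"].to_numpy()[host],
        }
    )

    # Scored polygons: random rectangles clipped to the grid extent.
    polys, scores = [], []
    for _ in range(config.n_polygons):
        cx, cy = rng.uniform(0.15, 0.85, 2) * np.array([nx * cs, ny * cs])
        w, h = rng.uniform(1.5, 4.5, 2) * cs
        polys.append(box(cx - w, cy - h, cx + w, cy + h))
        scores.append(float(np.clip(rng.normal(0.0, 1.0), -2.5, 2.5)))
    polygons = pd.DataFrame(
        {
            "unit_id": [f"U{i:02d}" for i in range(config.n_polygons)],
            "geometry": polys,
            "marginalization": scores,
        }
    )

    # Population raster: coarser grid, deliberately offset from the model grid.
    pdx = pdy = cs * 1.2
    x0, y0 = -0.37 * pdx, -0.41 * pdy
    pnx = int(np.ceil((nx * cs - x0) / pdx)) + 1
    pny = int(np.ceil((ny * cs - y0) / pdy)) + 1
    dens_field = _smooth_field(rng, (pny, pnx), config.spatial_corr_cells)
    density = np.exp(0.8 * dens_field)
    total_area_km2 = pdx * pdy / 1e6 * density.size
    density *= config.population_total / (density.mean() * total_area_km2)
    population = PopulationRaster(x0=x0, y0=y0, dx=pdx, dy=pdy, density=density)

    return RegionFixture(
        cells=cells,
        cell_size=cs,
        stations=stations,
        polygons=polygons,
        population=population,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# latent truth

def make_truth(fixture: RegionFixture, config: SyntheticConfig | None = None,
               seed: int | None = None) -> TruthField:
    """Latent daily-mean PM2.5 per cell-day plus a peaked hourly profile.

    Log-scale mean = base + season effect + static smooth spatial pattern +
    AR(1) regional day effect + a day-varying smooth spatial anomaly (the
    synoptic component: ventilation and boundary-layer weather that moves
    across the domain from day to day) + unstructured cell-day noise;
    rainy-season days are lower on average by construction.  The hourly
    profile is a Gaussian bump at the configured peak hour, normalized to
    unit mean, with a small day-specific jitter.
    """
    config = config or SyntheticConfig()
    seed = (config.seed + 1) if seed is None else seed
    rng = np.random.default_rng(seed)

    n_days = config.n_years * 365
    dates = pd.date_range(config.start_date, periods=n_days, freq="D")
    season = season_of_dates(dates)
    cells = fixture.cells
    n_cells = len(cells)

    full = _smooth_field(rng, (config.ny, config.nx), config.spatial_corr_cells)
    spatial = config.spatial_sd * full[cells["row"].to_numpy(), cells["col"].to_numpy()]

    day_eff = np.empty(n_days)
    rho = 0.6
    innov = rng.standard_normal(n_days) * config.daily_sd * np.sqrt(1 - rho**2)
    day_eff[0] = rng.standard_normal() * config.daily_sd
    for t in range(1, n_days):
        day_eff[t] = rho * day_eff[t - 1] + innov[t]

    season_eff = np.array([config.season_log_effect[s] for s in season])
    synoptic = np.empty((n_days, n_cells))
    rc = (cells["row"].to_numpy(), cells["col"].to_numpy())
    for t in range(n_days):
        synoptic[t] = _smooth_field(rng, (config.ny, config.nx),
                                    config.synoptic_corr_cells)[rc]
    cellday = rng.standard_normal((n_days, n_cells)) * config.cellday_sd
    log_mean = (
        np.log(config.base_pm)
        + season_eff[:, None]
        + day_eff[:, None]
        + spatial[None, :]
        + config.synoptic_sd * synoptic
        + cellday
    )
    mean = np.exp(log_mean)

    hours = np.arange(24)
    base = 1.0 + config.peak_amplitude * np.exp(
        -0.5 * ((hours - config.peak_hour) / 2.5) ** 2
    )
    jitter = 1.0 + config.profile_jitter * rng.standard_normal((n_days, 24))
    profile = base[None, :] * jitter
    profile = np.maximum(profile, 0.05)
    profile /= profile.mean(axis=1, keepdims=True)

    return TruthField(
        dates=dates, cell_ids=cells["cell_id"].to_numpy(),
        mean=mean, hourly_profile=profile, season=season,
    )


# ---------------------------------------------------------------------------
# observations

def simulate_observations(
    fixture: RegionFixture,
    truth: TruthField,
    missingness: float | None = None,
    seed: int | None = None,
    noise_sigma: float | None = None,
    config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Hourly station records: truth x hourly profile x lognormal noise.

    Each station-hour is independently dropped at the missingness rate, so
    some station-days fall below the 18-hour completeness rule whenever
    missingness is appreciable.  The lognormal noise has unit mean so the
    noiseless limit reproduces the truth mean exactly.
    """
    config = config or SyntheticConfig()
    missingness = config.missingness if missingness is None else missingness
    noise_sigma = config.noise_sigma if noise_sigma is None else noise_sigma
    seed = (config.seed + 2) if seed is None else seed
    if not 0 <= missingness < 1:
        raise ValueError("missingness must be in [0, 1)")
    rng = np.random.default_rng(seed)

    cell_pos = {c: i for i, c in enumerate(truth.cell_ids)}
    host = np.array([cell_pos[c] for c in fixture.stations["cell_id"]])
    n_days, n_st = len(truth.dates), len(fixture.stations)

    # (n_days, n_stations, 24)
    base = truth.mean[:, host][:, :, None] * truth.hourly_profile[:, None, :]
    if noise_sigma > 0:
        noise = np.exp(
            rng.normal(-0.5 * noise_sigma**2, noise_sigma, size=base.shape)
        )
    else:
        noise = 1.0
    values = base * noise
    keep = rng.random(base.shape) >= missingness

    d_idx, s_idx, h_idx = np.nonzero(keep)
    return pd.DataFrame(
        {
            "station_id": fixture.stations["station_id"].to_numpy()[s_idx],
            "date": truth.dates[d_idx],
            "hour": h_idx,
            "pm25": values[d_idx, s_idx, h_idx],
        }
    )


# ---------------------------------------------------------------------------
# predictors

def _blend(rng, s: np.ndarray, w: float, corr_cells: float, shape_full, rows, cols) -> np.ndarray:
    """w * standardized-truth + sqrt(1-w^2) * fresh smooth noise (unit variance)."""
    n_days = s.shape[0]
    noise = np.empty_like(s)
    for d in range(n_days):
        full = _smooth_field(rng, shape_full, corr_cells)
        noise[d] = full[rows, cols]
    return w * s + np.sqrt(max(0.0, 1.0 - w**2)) * noise


def simulate_predictors(
    fixture: RegionFixture,
    truth: TruthField,
    informativeness: float | None = None,
    seed: int | None = None,
    config: SyntheticConfig | None = None,
) -> PredictorFields:
    """Gridded predictor fields as monotone transforms of truth blended with noise.

    At informativeness 1 every dynamic predictor is a strictly monotone
    function of the latent truth mean; at 0 it is independent smooth noise.
    Satellite AOD layers carry missing cells on a random subset of days.
    Boundary-layer height is anticorrelated with PM (stable, shallow layers
    trap particles).  Temperature is emitted as separate daily max and min
    layers; its coupling to PM is a signed config knob.  Mid-morning
    (``hour``) variants of the sub-daily fields are emitted for the
    daily-max model.
    """
    config = config or SyntheticConfig()
    w = config.informativeness if informativeness is None else informativeness
    if not 0 <= w <= 1:
        raise ValueError("informativeness must be in [0, 1]")
    seed = (config.seed + 3) if seed is None else seed
    rng = np.random.default_rng(seed)

    cells = fixture.cells
    rows, cols = cells["row"].to_numpy(), cells["col"].to_numpy()
    shape_full = (config.ny, config.nx)
    n_days, n_cells = truth.mean.shape

    log_m = np.log(truth.mean)
    s = (log_m - log_m.mean()) / log_m.std()

    def blended():
        return _blend(rng, s, w, config.spatial_corr_cells, shape_full, rows, cols)

    daily = {}
    daily["aod_terra"] = np.exp(-1.2 + 0.45 * blended())
    daily["aod_aqua"] = np.exp(-1.3 + 0.50 * blended())
    daily["modeled_pm"] = 25.0 * np.exp(0.4 * blended())
    daily["pbl_height"] = 1100.0 * np.exp(-0.35 * blended())
    daily["wind_u"] = 2.0 * (0.3 * -blended() + rng.standard_normal((n_days, n_cells)) * 0.7)
    daily["wind_v"] = 2.0 * (0.3 * -blended() + rng.standard_normal((n_days, n_cells)) * 0.7)

    # Temperature: seasonal cycle + signed coupling to the PM anomaly.
    doy = truth.dates.dayofyear.to_numpy()
    seasonal_c = 16.0 + 4.0 * np.sin(2 * np.pi * (doy - 120) / 365.0)
    tmean_c = (
        seasonal_c[:, None]
        + config.temp_pm_coupling * s
        + 1.5 * _blend(rng, np.zeros_like(s), 0.0, config.spatial_corr_cells,
                       shape_full, rows, cols)
    )
    diurnal_half_range = 7.0
    daily["temp_max"] = tmean_c + diurnal_half_range + 273.15
    daily["temp_min"] = tmean_c - diurnal_half_range + 273.15

    daily["vapor_pressure"] = 1500.0 + 450.0 * np.sin(2 * np.pi * (doy[:, None] - 60) / 365.0) \
        + 120.0 * rng.standard_normal((n_days, n_cells))

    rainy = truth.season == "rainy"
    wet_day = rainy & (rng.random(n_days) < config.rain_wet_prob)
    amounts = rng.gamma(shape=1.5, scale=config.rain_mean_mm / 1.5, size=(n_days, n_cells))
    precip = np.where(wet_day[:, None], amounts, 0.0)
    daily["precipitation"] = precip

    # AOD coverage gaps: on gap days a random fraction of cells is missing.
    for name in ("aod_terra", "aod_aqua"):
        gap_day = rng.random(n_days) < config.aod_gap_day_prob
        frac = rng.uniform(0.0, config.aod_gap_max_frac, size=n_days)
        gaps = rng.random((n_days, n_cells)) < (gap_day * frac)[:, None]
        layer = daily[name].copy()
        layer[gaps] = np.nan
        daily[name] = layer

    # Mid-morning variants of the sub-daily fields: daily value perturbed by
    # fresh noise, plus the mid-morning profile uplift for modeled PM.
    uplift = truth.hourly_profile[:, config.peak_hour][:, None]
    at_hour = {
        "modeled_pm": daily["modeled_pm"] * uplift
        * np.exp(0.1 * rng.standard_normal((n_days, n_cells))),
        "pbl_height": daily["pbl_height"]
        * np.exp(0.15 * rng.standard_normal((n_days, n_cells))),
        "wind_u": daily["wind_u"] + 0.5 * rng.standard_normal((n_days, n_cells)),
        "wind_v": daily["wind_v"] + 0.5 * rng.standard_normal((n_days, n_cells)),
    }

    road_full = _smooth_field(rng, shape_full, config.spatial_corr_cells)
    spatial_pattern = (s.mean(axis=0) - s.mean()) / max(s.mean(axis=0).std(), 1e-12)
    road = 5000.0 * np.exp(0.5 * w * spatial_pattern
                           + 0.5 * np.sqrt(max(0.0, 1 - w**2)) * road_full[rows, cols])
    static = {"road_density": road}

    return PredictorFields(
        dates=truth.dates, cell_ids=truth.cell_ids,
        daily=daily, at_hour=at_hour, static=static, hour=config.peak_hour,
    )


def temperature_celsius(predictors: PredictorFields) -> np.ndarray:
    """Daily-mean temperature surface in degC: (max + min)/2 of the K layers."""
    return (predictors.daily["temp_max"] + predictors.daily["temp_min"]) / 2.0 - 273.15


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """One call producing the full synthetic study from ``config.seed``."""
    config = config or SyntheticConfig()
    fixture = make_fixture(config)
    truth = make_truth(fixture, config)
    records = simulate_observations(fixture, truth, config=config)
    predictors = simulate_predictors(fixture, truth, config=config)
    return SyntheticDataset(config=config, fixture=fixture, truth=truth,
                            records=records, predictors=predictors)
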