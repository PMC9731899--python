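import numpy as np
import pandas as pd
import pytest

from aerosurf import synthetic_data as sd
from aerosurf.station_ingest import aggregate_station_days


@pytest.fixture(scope="session")
def small_config():
    """A miniature study: 1 year, 12x12 grid, 5 stations."""
    return sd.SyntheticConfig(nx=12, ny=12, n_stations=5, n_years=1,
                              n_polygons=4, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.generate(small_config)


@pytest.fixture(scope="session")
def small_station_days(small_dataset):
    return aggregate_station_days(small_dataset.records)


@pytest.fixture(scope="session")
def tiny_predictors():
    """Hand-built predictor fields: 3 cells, 4 days, constant layers."""
    dates = pd.date_range("2018-01-01", periods=4)
    cell_ids = np.array([0, 1, 2])
    shape = (4, 3)
    daily = {
        "aod_terra": np.full(shape, 0.3),
        "aod_aqua": np.full(shape, 0.25),
        "modeled_pm": np.full(shape, 20.0),
        "temp_max": np.full(shape, 295.0),
        "temp_min": np.full(shape, 281.0),
        "precipitation": np.zeros(shape),
        "vapor_pressure": np.full(shape, 1500.0),
        "pbl_height": np.full(shape, 1000.0),
        "wind_u": np.full(shape, 1.0),
        "wind_v": np.full(shape, -1.0),
    }
    at_hour = {
        "modeled_pm": np.full(shape, 35.0),
        "pbl_height": np.full(shape, 700.0),
        "wind_u": np.full(shape, 2.0),
        "wind_v": np.full(shape, -2.0),
    }
    static = {"road_density": np.array([100.0, 200.0, 300.0])}
    return sd.PredictorFields(dates=dates, cell_ids=cell_ids, daily=daily,
                              at_hour=at_hour, static=static, hour=10)


@pytest.fixture(scope="session")
def tiny_stations():
    return pd.DataFrame(
        {"station_id": ["A", "B"], "x": [500.0, 2500.0], "y": [500.0, 500.0],
         "cell_id": [0, 2]}
    )
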