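import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pmbme.covariance import CovarianceModel, PM25_NESTED_MODEL
from pmbme.geodata import LanduseMap


@pytest.fixture
def nested_model() -> CovarianceModel:
    """Reference nested covariance for monthly urban PM2.5."""
    return PM25_NESTED_MODEL


@pytest.fixture
def square_road_map() -> LanduseMap:
    """A single 2 km x 2 km road polygon centered at (1, 1) km."""
    return LanduseMap(geoms=[box(0, 0, 2, 2)], classes=["road"])


@pytest.fixture
def toy_pm_series() -> pd.DataFrame:
    rows = []
    for sid, base in (("s1", 30.0), ("s2", 40.0), ("s3", 35.0)):
        for t in range(4):
            rows.append({"station_id": sid, "month": t, "pollutant": "pm10",
                         "value": base + t})
            rows.append({"station_id": sid, "month": t, "pollutant": "pm25",
                         "value": 0.6 * (base + t)})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_stations() -> pd.DataFrame:
    return pd.DataFrame({
        "station_id": ["s1", "s2", "s3"],
        "x": [5.0, 15.0, 10.0],
        "y": [5.0, 10.0, 18.0],
        "roles": ["pm25;pm10", "pm25;pm10", "pm25;pm10"],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
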