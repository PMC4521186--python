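import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from coastspan.coast_range import Coastline
from coastspan.env_climatology import ClimatologyGrid, ClimatologySet
from coastspan.synthetic_world import MONTH_BLOCKS


@pytest.fixture
def meridian():
    """Straight meridional coastline along lon=0 from lat 0 to 10."""
    lats = np.arange(0.0, 10.5, 1.0)
    return Coastline(id="meridian", lats=lats, lons=np.zeros_like(lats))


@pytest.fixture
def wiggly_coast():
    """Coastline with longitude jitter, for projection oracle tests."""
    rng = np.random.default_rng(7)
    lats = np.arange(-10.0, 30.5, 1.0)
    lons = 5.0 + rng.normal(0.0, 0.2, lats.size)
    return Coastline(id="wiggly", lats=lats, lons=lons, basin="test")


def constant_grid_set(values: dict[str, float], lat0=-10, lat1=10,
                      lon0=-5, lon1=5) -> ClimatologySet:
    """Grids constant in space, one value per (variable, block)."""
    lat_edges = np.arange(lat0, lat1 + 1e-9)
    lon_edges = np.arange(lon0, lon1 + 1e-9)
    shape = (len(lat_edges) - 1, len(lon_edges) - 1)
    grids = []
    for (var, block), value in values.items():
        grids.append(
            ClimatologyGrid(var, MONTH_BLOCKS[block], lat_edges, lon_edges,
                            np.full(shape, value))
        )
    return ClimatologySet(grids)


@pytest.fixture
def occurrences_df():
    def make(rows):
        return pd.DataFrame(rows, columns=["species_id", "lat", "lon", "source"])
    return make
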