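import numpy as np
import pandas as pd
import pytest
import xarray as xr

from npptrends.grid import GeoGrid, cell_areas
from npptrends.synthetic import month_axis


@pytest.fixture
def grid10():
    return GeoGrid.regular(10.0)


@pytest.fixture
def areas10(grid10):
    return cell_areas(grid10)


def make_series(values, start="2000-01", units="mg C m-2 d-1",
                lat=None, lon=None):
    """Wrap a (time, lat, lon) array as the package's field-series DataArray."""
    values = np.asarray(values, dtype=float)
    n, nlat, nlon = values.shape
    time = month_axis(start, n)
    if lat is None:
        lat = np.linspace(-90 + 90 / nlat, 90 - 90 / nlat, nlat)
    if lon is None:
        lon = np.linspace(-180 + 180 / nlon, 180 - 180 / nlon, nlon)
    return xr.DataArray(values, dims=("time", "lat", "lon"),
                        coords={"time": time, "lat": lat, "lon": lon},
                        attrs={"units": units}, name="field")


@pytest.fixture
def make_field():
    return make_series
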