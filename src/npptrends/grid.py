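"""Grid geometry, cell areas, masks, area-weighted reductions, and netCDF I/O.

Gridded monthly fields are represented throughout the package as
:class:`xarray.DataArray` objects with dims ``("time", "lat", "lon")`` (or
``("lat", "lon")`` for static fields), a ``units`` attribute, and NaN marking
missing data.  This module owns the geometry: the equal-angle
:class:`GeoGrid`, spherical cell areas, area-weighted reductions that respect
an ocean mask and the missing-data mask, and aggregation onto a near-equal-area
grid of ~fixed-size cells (used by the EOF stage so meridian convergence does
not bias the variance decomposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import ConfigError, EmptyDomainError, FormatError, InvalidGridError

#: Mean spherical Earth radius in metres.  Area weighting is insensitive to
#: the ellipsoid at the precision of this analysis.
EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "GeoGrid",
    "EqualAreaGrid",
    "EqualAreaField",
    "cell_areas",
    "area_weighted_mean",
    "downsample_equal_area",
    "read_fields",
    "write_fields",
]


@dataclass(frozen=True)
class GeoGrid:
    """Equal-angle latitude/longitude grid defined by its cell edges.

    Cell-center registration: a grid with edges ``[-90, ..., 90]`` and
    ``[-180, ..., 180]`` has centers at the midpoints, matching NASA L3
    ocean-color conventions.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_edges, dtype=float)
        lon = np.asarray(self.lon_edges, dtype=float)
        object.__setattr__(self, "lat_edges", lat)
        object.__setattr__(self, "lon_edges", lon)
        for name, edges in (("lat", lat), ("lon", lon)):
            if edges.ndim != 1 or edges.size < 2:
                raise InvalidGridError(f"{name}_edges must be 1-D with >= 2 entries")
            if not np.all(np.diff(edges) > 0):
                raise InvalidGridError(f"{name}_edges must be strictly increasing")
        if lat[0] < -90.0 - 1e-9 or lat[-1] > 90.0 + 1e-9:
            raise InvalidGridError("lat_edges must lie within [-90, 90]")
        if lon[0] < -180.0 - 1e-9 or lon[-1] > 180.0 + 1e-9:
            raise InvalidGridError("lon_edges must lie within [-180, 180]")

    @classmethod
    def regular(cls, resolution_deg: float) -> "GeoGrid":
        """Global grid of square cells, e.g. ``regular(1/12)`` for 1/12 degree."""
        if resolution_deg <= 0:
            raise InvalidGridError("resolution must be positive")
        nlat = round(180.0 / resolution_deg)
        nlon = round(360.0 / resolution_deg)
        return cls(
            lat_edges=np.linspace(-90.0, 90.0, nlat + 1),
            lon_edges=np.linspace(-180.0, 180.0, nlon + 1),
        )

    @property
    def nlat(self) -> int:
        return self.lat_edges.size - 1

    @property
    def nlon(self) -> int:
        return self.lon_edges.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def coords(self) -> dict[str, np.ndarray]:
        return {"lat": self.lat_centers, "lon": self.lon_centers}

    @classmethod
    def from_coords(cls, lat: np.ndarray, lon: np.ndarray) -> "GeoGrid":
        """Reconstruct a regular grid from cell-center coordinates."""

        def edges(c: np.ndarray) -> np.ndarray:
            c = np.asarray(c, dtype=float)
            if c.size == 1:
                raise InvalidGridError("cannot infer edges from a single center")
            mid = 0.5 * (c[:-1] + c[1:])
            first = c[0] - (mid[0] - c[0])
            last = c[-1] + (c[-1] - mid[-1])
            return np.concatenate([[first], mid, [last]])

        return cls(lat_edges=edges(lat), lon_edges=edges(lon))


def cell_areas(grid: GeoGrid, radius_m: float = EARTH_RADIUS_M) -> xr.DataArray:
    """Spherical zone area of every grid cell in m^2.

    area = R^2 * dlon * (sin(lat2) - sin(lat1)), angles in radians.
    """
    lat_r = np.deg2rad(grid.lat_edges)
    lon_r = np.deg2rad(grid.lon_edges)
    band = radius_m**2 * (np.sin(lat_r[1:]) - np.sin(lat_r[:-1]))
    areas = np.outer(band, np.diff(lon_r))
    return xr.DataArray(
        areas, dims=("lat", "lon"), coords=grid.coords(), attrs={"units": "m2"}
    )


def _broadcast_valid(field: xr.DataArray) -> np.ndarray:
    return np.isfinite(field.values)


def area_weighted_mean(
    field: xr.DataArray,
    areas: xr.DataArray,
    mask: xr.DataArray | None = None,
) -> float | xr.DataArray:
    """Area-weighted mean over (lat, lon), respecting mask and missing data.

    For a ``(time, lat, lon)`` field returns a per-time series; for a static
    ``(lat, lon)`` field returns a scalar.  Raises
    :class:`~npptrends.exceptions.EmptyDomainError` when no valid cell exists.
    """
    w = areas.values.astype(float)
    if mask is not None:
        w = w * mask.values.astype(float)
    vals = field.values
    valid = np.isfinite(vals)
    if vals.ndim == 2:
        wv = w * valid
        tot = wv.sum()
        if tot <= 0:
            raise EmptyDomainError("no valid cells in area-weighted mean")
        return float(np.nansum(wv * np.where(valid, vals, 0.0)) / tot)
    # (time, lat, lon): reduce per time step
    wv = w[None, :, :] * valid
    tot = wv.sum(axis=(1, 2))
    if np.all(tot <= 0):
        raise EmptyDomainError("no valid cells in area-weighted mean")
    num = (wv * np.where(valid, vals, 0.0)).sum(axis=(1, 2))
    out = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), np.nan)
    return xr.DataArray(out, dims=("time",), coords={"time": field.time}, attrs=dict(field.attrs))


# ---------------------------------------------------------------------------
# Near-equal-area aggregation grid
# ---------------------------------------------------------------------------

@dataclass
class EqualAreaGrid:
    """Latitude bands of fixed meridional extent, each split into longitude
    cells of approximately the same zonal extent, so all cells have ~equal
    area (ragged rows flattened to a 1-D cell index)."""

    lat_band_edges: np.ndarray          # (nband + 1,)
    nlon_per_band: np.ndarray           # (nband,) int
    cell_lat: np.ndarray                # (ncell,) center latitude
    cell_lon: np.ndarray                # (ncell,) center longitude
    band_of_cell: np.ndarray            # (ncell,) int
    target_cell_km: float

    @property
    def ncell(self) -> int:
        return self.cell_lat.size

    @classmethod
    def build(cls, target_cell_km: float, radius_m: float = EARTH_RADIUS_M) -> "EqualAreaGrid":
        if target_cell_km <= 0:
            raise ConfigError("target cell size must be positive")
        dphi = np.rad2deg(target_cell_km * 1000.0 / radius_m)
        nband = max(1, round(180.0 / dphi))
        band_edges = np.linspace(-90.0, 90.0, nband + 1)
        band_centers = 0.5 * (band_edges[:-1] + band_edges[1:])
        circ_km = 2 * np.pi * radius_m / 1000.0 * np.cos(np.deg2rad(band_centers))
        nlon = np.maximum(1, np.round(circ_km / target_cell_km).astype(int))
        cell_lat, cell_lon, band_of = [], [], []
        for b in range(nband):
            lon_edges = np.linspace(-180.0, 180.0, nlon[b] + 1)
            centers = 0.5 * (lon_edges[:-1] + lon_edges[1:])
            cell_lat.append(np.full(nlon[b], band_centers[b]))
            cell_lon.append(centers)
            band_of.append(np.full(nlon[b], b, dtype=int))
        return cls(
            lat_band_edges=band_edges,
            nlon_per_band=nlon,
            cell_lat=np.concatenate(cell_lat),
            cell_lon=np.concatenate(cell_lon),
            band_of_cell=np.concatenate(band_of),
            target_cell_km=target_cell_km,
        )

    def flat_index(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Flat cell index of points given by (lat, lon) in degrees."""
        offsets = np.concatenate([[0], np.cumsum(self.nlon_per_band)])
        b = np.clip(
            np.searchsorted(self.lat_band_edges, lat, side="right") - 1,
            0,
            self.nlon_per_band.size - 1,
        )
        nl = self.nlon_per_band[b]
        j = np.clip(((lon + 180.0) / 360.0 * nl).astype(int), 0, nl - 1)
        return offsets[b] + j


@dataclass
class EqualAreaField:
    """A (time x cell) field on an :class:`EqualAreaGrid`.

    ``cell_area`` is the summed source-cell area contributing to each target
    cell, so that area-weighted means computed on this field agree exactly
    with those on the source grid when the source field is fully valid.
    """

    grid: EqualAreaGrid
    values: np.ndarray                  # (ntime, ncell) or (ncell,)
    cell_area: np.ndarray               # (ncell,) m^2
    time: pd.DatetimeIndex | None = None
    units: str = ""
    attrs: dict = field(default_factory=dict)

    @property
    def ncell(self) -> int:
        return self.cell_area.size


def downsample_equal_area(
    field_da: xr.DataArray,
    areas: xr.DataArray,
    target_cell_km: float = 50.0,
    mask: xr.DataArray | None = None,
) -> EqualAreaField:
    """Aggregate an equal-angle field onto a near-equal-area grid.

    Every source cell contributes wholly to the target cell containing its
    center; target values are area-weighted means of valid contributors and
    missing where all contributors are missing.  Target cells receiving no
    (ocean) source area are dropped.
    """
    if target_cell_km <= 0:
        raise ConfigError("target cell size must be positive")
    ea = EqualAreaGrid.build(target_cell_km)
    grid = GeoGrid.from_coords(field_da.lat.values, field_da.lon.values)
    lat2, lon2 = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    idx = ea.flat_index(lat2.ravel(), lon2.ravel())

    w = areas.values.astype(float)
    if mask is not None:
        w = w * mask.values.astype(float)
    w = w.ravel()

    ncell = ea.ncell
    tot_area = np.bincount(idx, weights=w, minlength=ncell)
    keep = tot_area > 0

    vals = field_da.values
    single = vals.ndim == 2
    if single:
        vals = vals[None, ...]
    ntime = vals.shape[0]
    out = np.full((ntime, ncell), np.nan)
    for t in range(ntime):
        v = vals[t].ravel()
        ok = np.isfinite(v) & (w > 0)
        wsum = np.bincount(idx[ok], weights=w[ok], minlength=ncell)
        vsum = np.bincount(idx[ok], weights=(w * np.where(np.isfinite(v), v, 0.0))[ok], minlength=ncell)
        good = wsum > 0
        out[t, good] = vsum[good] / wsum[good]

    sub = EqualAreaGrid(
        lat_band_edges=ea.lat_band_edges,
        nlon_per_band=ea.nlon_per_band,
        cell_lat=ea.cell_lat[keep],
        cell_lon=ea.cell_lon[keep],
        band_of_cell=ea.band_of_cell[keep],
        target_cell_km=target_cell_km,
    )
    out = out[:, keep]
    if single:
        out = out[0]
    time = pd.DatetimeIndex(field_da.time.values) if "time" in field_da.dims else None
    return EqualAreaField(
        grid=sub,
        values=out,
        cell_area=tot_area[keep],
        time=time,
        units=str(field_da.attrs.get("units", "")),
    )


# ---------------------------------------------------------------------------
# netCDF I/O
# ---------------------------------------------------------------------------

def write_fields(series: xr.DataArray, path, variable: str | None = None) -> None:
    """Write a field series to netCDF (CF-style lat/lon/time, units attr)."""
    name = variable or series.name or "field"
    if "units" not in series.attrs:
        raise FormatError("field series must carry a 'units' attribute")
    ds = series.to_dataset(name=name)
    ds.to_netcdf(path, engine="scipy")


def read_fields(path, variable: str) -> xr.DataArray:
    """Read a field series from netCDF, returning it time-sorted.

    Raises :class:`FormatError` when coordinates or the units attribute are
    absent.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not present in {path}")
        da = ds[variable].load()
    for coord in ("lat", "lon"):
        if coord not in da.coords:
            raise FormatError(f"missing coordinate {coord!r} in {path}")
    if "units" not in da.attrs:
        raise FormatError(f"variable {variable!r} lacks a units attribute")
    if "time" in da.dims:
        times = pd.DatetimeIndex(da.time.values)
        if times.has_duplicates:
            raise FormatError("duplicate time stamps in file")
        if not times.is_monotonic_increasing:
            da = da.sortby("time")
    return da
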