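"""Synthetic multi-year monthly ocean-color datasets with known truth.

The generator emulates the statistical structure of satellite ocean-color
records so every downstream stage (blending, deseasonalization, trend
inference, EOF analysis, global budgets) can be scored against a planted
truth without any downloads:

* a 12-month seasonal cycle whose amplitude grows with latitude and whose
  phase flips across the equator;
* spatially varying linear trends (e.g. sign flipping across a mean-SST
  isotherm, mirroring the transition between seasonally mixing and
  permanently stratified biomes);
* AR(1) residual noise, initialized from its stationary distribution so no
  burn-in transient biases trend tests;
* planted spatial modes driven by index time series (for EOF recovery);
* missing data from random cloud cover plus polar night (cells where the
  synthetic PAR field falls below 1 mol photons m-2 d-1);
* a stationary per-calendar-month inter-mission bias for blending tests.

NPP is constructed exactly as PAR x (aphi/a) x phi_mu and the growth rate as
mu = NPP / Cphyto, so the multiplicative identity holds to machine precision
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import ConfigError
from .grid import GeoGrid

__all__ = [
    "PlantedMode",
    "ComponentSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_ocean_mask",
    "month_axis",
    "generate_field",
    "generate_dataset",
    "generate_two_missions",
]

#: PAR below which a cell-month is treated as polar night (mol photons m-2 d-1).
POLAR_NIGHT_PAR = 1.0


def month_axis(start: str, n_months: int) -> pd.DatetimeIndex:
    """Calendar-month time axis stamped at mid-month (the 15th)."""
    return pd.date_range(start, periods=n_months, freq="MS") + pd.Timedelta(days=14)


def default_ocean_mask(grid: GeoGrid) -> np.ndarray:
    """A synthetic land/ocean mask: two idealized continents covering ~30%
    of the globe, so area-weighted reductions are exercised with real holes."""
    lat, lon = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    continent1 = (lat > -35) & (lat < 70) & (lon > -100) & (lon < -40)
    continent2 = (lat > -35) & (lat < 75) & (lon > 10) & (lon < 100)
    return ~(continent1 | continent2)


@dataclass
class PlantedMode:
    """A separable space-time mode: loading * pattern(x) * index(t)."""

    pattern: np.ndarray          # (nlat, nlon)
    index: np.ndarray            # (n_months,)
    loading: float = 1.0
    name: str = "mode"


@dataclass
class ComponentSpec:
    """Statistical recipe for one gridded component.

    The monthly value at cell x, month t is

        clim(x, month(t)) + slope(x) * t_dec + sum_m loading_m pattern_m(x) index_m(t)
        + AR(1) noise

    where clim = mean_field + amplitude_field * cos(2 pi (month - phase)/12),
    the seasonal phase flips by 6 months across the equator, and t_dec is time
    in decades centered on the record midpoint (so the planted slope is the
    OLS-recoverable decadal trend).  With ``lognormal=True`` the structure is
    generated in log space and exponentiated around the mean climatology.
    """

    name: str
    units: str
    mean: float
    equator_excess: float = 0.0          # added to mean, scaled by cos(lat)
    seasonal_amplitude: float = 0.0      # scaled by |sin(lat)|
    phase_month: float = 7.0             # month of seasonal max, northern hemisphere
    trend_per_decade: float | np.ndarray = 0.0
    rho: float = 0.0
    innovation_sd: float = 0.0
    modes: list[PlantedMode] = dc_field(default_factory=list)
    floor: float | None = None
    lognormal: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError(f"{self.name}: rho must be in [0, 1), got {self.rho}")
        if self.innovation_sd < 0:
            raise ConfigError(f"{self.name}: innovation SD must be >= 0")
        if self.seasonal_amplitude < 0:
            raise ConfigError(f"{self.name}: seasonal amplitude must be >= 0")


def _default_components() -> dict[str, ComponentSpec]:
    """Study-like base climatologies and noise levels for every component.

    Magnitudes give an NPP field of a few hundred mg C m-2 d-1 (the product
    of PAR ~ tens of mol photons m-2 d-1, an absorbed fraction ~ 0.05, and a
    carbon efficiency ~ hundreds of mg C per mol photons), growth rates of a
    few tenths per day, and polar-night PAR shutdown in winter at high
    latitude.
    """
    return {
        "par": ComponentSpec("par", "mol photons m-2 d-1", mean=8.0,
                             equator_excess=32.0, seasonal_amplitude=22.0,
                             rho=0.3, innovation_sd=1.0, floor=0.0),
        "aphi_frac": ComponentSpec("aphi_frac", "1", mean=0.055,
                                   equator_excess=-0.01, seasonal_amplitude=0.004,
                                   rho=0.3, innovation_sd=0.002, floor=1e-4),
        "phimu": ComponentSpec("phimu", "mg C (mol photons)-1", mean=280.0,
                               equator_excess=40.0, seasonal_amplitude=15.0,
                               rho=0.3, innovation_sd=8.0, floor=1.0),
        "aphi": ComponentSpec("aphi", "m-1", mean=0.02, equator_excess=-0.005,
                              seasonal_amplitude=0.002, rho=0.3,
                              innovation_sd=0.001, floor=1e-5),
        "adg": ComponentSpec("adg", "m-1", mean=0.012, equator_excess=-0.002,
                             seasonal_amplitude=0.001, rho=0.3,
                             innovation_sd=0.0008, floor=1e-5),
        "cphyto": ComponentSpec("cphyto", "mg C m-2", mean=1200.0,
                                equator_excess=-200.0, rho=0.4,
                                innovation_sd=0.05, lognormal=True),
        "sst": ComponentSpec("sst", "degC", mean=-1.5, equator_excess=29.0,
                             seasonal_amplitude=4.0, rho=0.8, innovation_sd=0.3),
        "mld": ComponentSpec("mld", "m", mean=60.0, equator_excess=-25.0,
                             seasonal_amplitude=30.0, phase_month=1.0,
                             rho=0.5, innovation_sd=5.0, floor=5.0),
        "below_frac": ComponentSpec("below_frac", "1", mean=0.25,
                                    seasonal_amplitude=0.03, rho=0.3,
                                    innovation_sd=0.01, floor=0.0),
    }


@dataclass
class SyntheticConfig:
    """Full recipe for a synthetic dataset; identical config + seed gives a
    bit-identical dataset."""

    grid: GeoGrid
    n_months: int = 300
    start: str = "1998-01"
    components: dict[str, ComponentSpec] = dc_field(default_factory=_default_components)
    cloud_fraction: float = 0.05
    polar_night_par: float = POLAR_NIGHT_PAR
    ocean_mask: np.ndarray | None = None
    bias_table: np.ndarray | None = None   # (12,) or (12, nlat, nlon)
    seed: int = 0

    def validate(self) -> None:
        if self.n_months < 24:
            raise ConfigError("need at least 24 months")
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ConfigError("cloud_fraction must be in [0, 1)")
        for spec in self.components.values():
            spec.validate()


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of downstream estimates."""

    slopes_per_decade: dict[str, np.ndarray]      # per component, (nlat, nlon)
    climatology: dict[str, np.ndarray]            # per component, (12, nlat, nlon)
    modes: dict[str, list[PlantedMode]]
    noise: dict[str, tuple[float, float]]         # (rho, innovation_sd)
    ocean_mask: np.ndarray
    bias_table: np.ndarray | None
    missing_frac: float
    time: pd.DatetimeIndex


def _seasonal_phase(grid: GeoGrid, phase_month: float) -> np.ndarray:
    """Per-cell phase: northern-hemisphere value, +6 months south of the equator."""
    lat = grid.lat_centers
    phase = np.where(lat >= 0, phase_month, phase_month + 6.0)
    return np.broadcast_to(phase[:, None], (grid.nlat, grid.nlon))


def _component_climatology(spec: ComponentSpec, grid: GeoGrid) -> np.ndarray:
    lat = np.deg2rad(grid.lat_centers)
    meanf = spec.mean + spec.equator_excess * np.cos(lat)
    ampf = spec.seasonal_amplitude * np.abs(np.sin(lat))
    phase = _seasonal_phase(grid, spec.phase_month)
    months = np.arange(1, 13)
    clim = (meanf[None, :, None]
            + ampf[None, :, None] * np.cos(2 * np.pi * (months[:, None, None] - phase[None]) / 12.0))
    return np.broadcast_to(clim, (12, grid.nlat, grid.nlon)).copy()


def _ar1_noise(rng: np.random.Generator, rho: float, sd: float,
               shape: tuple) -> np.ndarray:
    """Stationary AR(1) noise: x_0 ~ N(0, sd^2/(1-rho^2))."""
    n = shape[0]
    out = np.empty(shape)
    if sd == 0:
        out.fill(0.0)
        return out
    out[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho**2), shape[1:])
    eps = rng.normal(0.0, sd, (n - 1,) + tuple(shape[1:]))
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t - 1]
    return out


def _generate_component(spec: ComponentSpec, grid: GeoGrid,
                        time: pd.DatetimeIndex,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (values (T, nlat, nlon), clim (12, nlat, nlon), slope map)."""
    spec.validate()
    n = time.size
    clim = _component_climatology(spec, grid)
    months = time.month.values
    tyears = time.year.values + (time.month.values - 0.5) / 12.0
    t_dec = (tyears - tyears.mean()) / 10.0

    slope = np.asarray(spec.trend_per_decade, dtype=float)
    if slope.ndim == 0:
        slope = np.full(grid.shape, float(slope))

    vals = clim[months - 1].copy() if not spec.lognormal else np.zeros((n,) + grid.shape)
    vals += slope[None] * t_dec[:, None, None]
    for mode in spec.modes:
        vals += mode.loading * mode.pattern[None] * np.asarray(mode.index)[:, None, None]
    vals += _ar1_noise(rng, spec.rho, spec.innovation_sd, (n,) + grid.shape)

    if spec.lognormal:
        base = clim[months - 1]
        vals = base * np.exp(vals)
    if spec.floor is not None:
        vals = np.maximum(vals, spec.floor)
    return vals, clim, slope


def _wrap(values: np.ndarray, grid: GeoGrid, time: pd.DatetimeIndex,
          units: str, name: str) -> xr.DataArray:
    return xr.DataArray(
        values, dims=("time", "lat", "lon"),
        coords={"time": time, **grid.coords()},
        attrs={"units": units}, name=name,
    )


def generate_field(
    grid: GeoGrid,
    n_months: int = 300,
    start: str = "1998-01",
    mean: float = 500.0,
    units: str = "mg C m-2 d-1",
    seasonal_amplitude: float = 0.0,
    trend_per_decade: float | np.ndarray = 0.0,
    rho: float = 0.0,
    innovation_sd: float = 0.0,
    modes: list[PlantedMode] | None = None,
    seed: int = 0,
) -> xr.DataArray:
    """Single synthetic field with a planted trend, modes, and AR(1) noise.

    Convenience generator for parameter-recovery experiments on one variable;
    :func:`generate_dataset` builds the full multi-component set.
    """
    spec = ComponentSpec("field", units, mean=mean,
                         seasonal_amplitude=seasonal_amplitude,
                         trend_per_decade=trend_per_decade,
                         rho=rho, innovation_sd=innovation_sd,
                         modes=modes or [])
    time = month_axis(start, n_months)
    rng = np.random.default_rng(seed)
    vals, _, _ = _generate_component(spec, grid, time, rng)
    return _wrap(vals, grid, time, units, "field")


def generate_dataset(config: SyntheticConfig) -> tuple[dict[str, xr.DataArray], SyntheticTruth]:
    """Generate the full component set plus its truth record.

    Derived fields are exact: npp = par * aphi_frac * phimu,
    mu = npp / cphyto, npp_below = below_frac * npp (so npp_below <= npp
    wherever below_frac <= 1).  Cloud and polar-night missingness is applied
    last, to all optically derived fields at once; SST and MLD come from
    other sensors and stay complete.  Land cells are missing everywhere.
    """
    config.validate()
    grid = config.grid
    time = month_axis(config.start, config.n_months)
    rng = np.random.default_rng(config.seed)
    ocean = config.ocean_mask if config.ocean_mask is not None else default_ocean_mask(grid)

    fields: dict[str, np.ndarray] = {}
    clims: dict[str, np.ndarray] = {}
    slopes: dict[str, np.ndarray] = {}
    for name in ["par", "aphi_frac", "phimu", "aphi", "adg", "cphyto",
                 "sst", "mld", "below_frac"]:
        spec = config.components[name]
        vals, clim, slope = _generate_component(spec, grid, time, rng)
        fields[name], clims[name], slopes[name] = vals, clim, slope

    below_frac = np.clip(fields.pop("below_frac"), 0.0, 0.95)
    fields["npp"] = fields["par"] * fields["aphi_frac"] * fields["phimu"]
    fields["mu"] = fields["npp"] / fields["cphyto"]
    fields["npp_below"] = below_frac * fields["npp"]

    # linearized planted NPP trend implied by the component trends
    par_bar = clims["par"].mean(axis=0)
    frac_bar = clims["aphi_frac"].mean(axis=0)
    phimu_bar = clims["phimu"].mean(axis=0)
    slopes["npp"] = (slopes["par"] * frac_bar * phimu_bar
                     + par_bar * slopes["aphi_frac"] * phimu_bar
                     + par_bar * frac_bar * slopes["phimu"])

    cloud = rng.random((config.n_months,) + grid.shape) < config.cloud_fraction
    polar = fields["par"] < config.polar_night_par
    missing = cloud | polar
    land = ~ocean

    optical = ["npp", "par", "aphi_frac", "phimu", "aphi", "adg",
               "cphyto", "mu", "npp_below"]
    units = {name: spec.units for name, spec in config.components.items()}
    units |= {"npp": "mg C m-2 d-1", "mu": "d-1", "npp_below": "mg C m-2 d-1"}

    out: dict[str, xr.DataArray] = {}
    for name, vals in fields.items():
        v = vals.copy()
        if name in optical:
            v[missing] = np.nan
        v[:, land] = np.nan
        out[name] = _wrap(v, grid, time, units[name], name)

    ocean3 = np.broadcast_to(ocean, missing.shape)
    truth = SyntheticTruth(
        slopes_per_decade=slopes,
        climatology=clims,
        modes={n: config.components[n].modes for n in config.components},
        noise={n: (config.components[n].rho, config.components[n].innovation_sd)
               for n in config.components},
        ocean_mask=ocean,
        bias_table=config.bias_table,
        missing_frac=float((missing & ocean3).sum() / max(ocean3.sum(), 1)),
        time=time,
    )
    return out, truth


def generate_two_missions(
    truth_field: xr.DataArray,
    bias_table: np.ndarray,
    a_range: tuple[str, str],
    b_range: tuple[str, str],
) -> tuple[xr.DataArray, xr.DataArray]:
    """Split one underlying series into two overlapping 'missions'.

    Mission B is the unbiased truth on its date range; mission A is truth plus
    a stationary per-calendar-month bias on its range.  Over the overlap both
    missions share the truth's noise realization, so a perfect blend recovers
    the truth exactly.  Requires >= 12 months of overlap (one full cycle of
    calendar months, the minimum to form monthly climatology differences).
    """
    bias = np.asarray(bias_table, dtype=float)
    if bias.shape[0] != 12:
        raise ConfigError("bias_table must have 12 leading entries (calendar months)")
    a = truth_field.sel(time=slice(*a_range)).copy(deep=True)
    b = truth_field.sel(time=slice(*b_range)).copy(deep=True)
    common = np.intersect1d(a.time.values, b.time.values)
    if common.size < 12:
        raise ConfigError(f"mission overlap is {common.size} months; need >= 12")
    months = pd.DatetimeIndex(a.time.values).month.values
    if bias.ndim == 1:
        a.values[:] = a.values + bias[months - 1][:, None, None]
    else:
        a.values[:] = a.values + bias[months - 1]
    a.name, b.name = "mission_a", "mission_b"
    return a, b
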