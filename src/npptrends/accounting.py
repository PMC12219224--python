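"""NPP component bookkeeping and global carbon budgets.

The absorption-based productivity model factors NPP multiplicatively into an
atmospheric, a bio-optical, and a physiological term,

    NPP = PAR * (aphi / a) * phi_mu ,

with the specific growth rate mu = NPP / Cphyto.  This module verifies that
identity on any component set, derives growth rates, integrates NPP to global
monthly/annual totals in Pg C (with climatological gap-filling restricted to
the sunlit domain), fits the trend of the annual totals, and tracks the
fraction of global NPP occurring beneath the surface mixed layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .exceptions import InsufficientDataError, UnitsError
from .trends import ClimatologySet

__all__ = [
    "GlobalSeries",
    "identity_residual",
    "growth_rate",
    "global_annual_npp",
    "fit_global_trend",
    "GlobalTrend",
    "below_mld_fraction",
]

#: mg C -> Pg C.
MG_TO_PG = 1e-18
#: PAR threshold delimiting the gap-fill (sunlit) domain, mol photons m-2 d-1.
GAPFILL_PAR_THRESHOLD = 1.0


@dataclass
class GlobalSeries:
    """Global NPP totals with gap-filling bookkeeping."""

    monthly: pd.Series         # Pg C per month (month totals, not rates)
    annual: pd.Series          # Pg C yr-1, indexed by calendar year
    gap_filled_fraction: pd.Series  # per month, fraction of integrated area filled
    unfilled_months: int = 0   # cell-months inside the fill domain lacking climatology


def identity_residual(npp: xr.DataArray, par: xr.DataArray,
                      aphi_frac: xr.DataArray, phimu: xr.DataArray) -> dict:
    """Residual statistics of NPP - PAR * (aphi/a) * phi_mu.

    Returns the max and mean |relative residual| over cells where all four
    fields are valid, relative to |NPP| (cells with NPP = 0 compare
    absolutely).  Raises :class:`UnitsError` on inconsistent units.
    """
    if npp.attrs.get("units") != "mg C m-2 d-1":
        raise UnitsError(f"npp units must be 'mg C m-2 d-1', got {npp.attrs.get('units')!r}")
    prod = par.values * aphi_frac.values * phimu.values
    resid = npp.values - prod
    ok = np.isfinite(resid) & np.isfinite(npp.values)
    scale = np.where(np.abs(npp.values) > 0, np.abs(npp.values), 1.0)
    rel = np.abs(resid[ok]) / scale[ok]
    if rel.size == 0:
        raise InsufficientDataError("no cells with all four components valid")
    return {
        "max_abs_relative_residual": float(rel.max()),
        "mean_abs_relative_residual": float(rel.mean()),
        "n": int(rel.size),
    }


def growth_rate(npp: xr.DataArray, cphyto: xr.DataArray) -> xr.DataArray:
    """mu = NPP / Cphyto (d-1); missing and counted where Cphyto <= 0."""
    c = cphyto.values
    bad = np.isfinite(c) & (c <= 0)
    mu_vals = np.where(np.isfinite(c) & (c > 0), npp.values / np.where(c > 0, c, 1), np.nan)
    mu = npp.copy(deep=True)
    mu.values = mu_vals
    mu.attrs = {"units": "d-1", "long_name": "phytoplankton specific growth rate",
                "n_nonpositive_cphyto": int(bad.sum())}
    mu.name = "mu"
    return mu


def _days_in_months(time: pd.DatetimeIndex) -> np.ndarray:
    return time.days_in_month.values.astype(float)


def global_annual_npp(
    npp: xr.DataArray,
    clim: ClimatologySet | None,
    par_clim: ClimatologySet | None,
    areas: xr.DataArray,
    mask: xr.DataArray | np.ndarray | None = None,
) -> GlobalSeries:
    """Global monthly and calendar-year NPP totals in Pg C.

    Monthly total = sum over ocean cells of NPP * area * days-in-month,
    mg C -> Pg C.  Where NPP is missing and the climatological PAR exceeds
    1 mol photons m-2 d-1 (the sunlit domain: cloud gaps, not polar night),
    the cell is filled with its NPP climatology; the area fraction filled is
    recorded per month.  Cells inside the fill domain that lack a climatology
    are counted and left unfilled.  Pass ``clim=None`` to disable filling.
    """
    time = pd.DatetimeIndex(npp.time.values)
    days = _days_in_months(time)
    w = areas.values.astype(float)
    if mask is not None:
        m = mask.values if isinstance(mask, xr.DataArray) else np.asarray(mask)
        w = w * m.astype(float)

    vals = npp.values.copy()
    filled_area = np.zeros(time.size)
    unfilled = 0
    if clim is not None:
        months = time.month.values
        clim_vals = clim.means.values            # (12, lat, lon)
        par_vals = par_clim.means.values if par_clim is not None else None
        for i, mo in enumerate(months):
            missing = ~np.isfinite(vals[i]) & (w > 0)
            domain = missing
            if par_vals is not None:
                domain = missing & (par_vals[mo - 1] > GAPFILL_PAR_THRESHOLD)
            fillable = domain & np.isfinite(clim_vals[mo - 1])
            vals[i][fillable] = clim_vals[mo - 1][fillable]
            unfilled += int((domain & ~np.isfinite(clim_vals[mo - 1])).sum())
            filled_area[i] = (w * fillable).sum()

    valid = np.isfinite(vals)
    monthly_pg = np.array([
        (w * np.where(valid[i], vals[i], 0.0)).sum() * days[i] * MG_TO_PG
        for i in range(time.size)
    ])
    integ_area = np.array([(w * valid[i]).sum() for i in range(time.size)])
    gap_frac = np.where(integ_area > 0, filled_area / np.where(integ_area > 0, integ_area, 1), 0.0)

    monthly = pd.Series(monthly_pg, index=time, name="npp_pg_per_month")
    annual = monthly.groupby(time.year).sum()
    complete = monthly.groupby(time.year).count() == 12
    annual = annual[complete]
    annual.name = "npp_pg_per_year"
    return GlobalSeries(
        monthly=monthly,
        annual=annual,
        gap_filled_fraction=pd.Series(gap_frac, index=time, name="gap_filled_fraction"),
        unfilled_months=unfilled,
    )


@dataclass
class GlobalTrend:
    """OLS fit of annual global totals against year."""

    slope_per_decade: float     # Pg C decade-1
    se_per_decade: float
    ci90_halfwidth: float       # Pg C decade-1, two-tailed 90%
    mean: float                 # Pg C yr-1 over the fitted years
    std: float
    net_percent_change: float   # 100 * slope_per_year * span / mean
    n_years: int


def fit_global_trend(gs: GlobalSeries, alpha: float = 0.10) -> GlobalTrend:
    """Trend of annual global NPP and the net percent change over the record.

    Net change is defined as the fitted slope times the record span divided
    by the record mean (one of several possible conventions; documented).
    """
    years = gs.annual.index.values.astype(float)
    vals = gs.annual.values.astype(float)
    ok = np.isfinite(vals)
    years, vals = years[ok], vals[ok]
    if years.size < 10:
        raise InsufficientDataError(f"need >= 10 annual values, got {years.size}")
    res = stats.linregress(years, vals)
    tcrit = stats.t.ppf(1 - alpha / 2, years.size - 2)
    span = years.max() - years.min()
    mean = float(vals.mean())
    return GlobalTrend(
        slope_per_decade=float(res.slope * 10),
        se_per_decade=float(res.stderr * 10),
        ci90_halfwidth=float(tcrit * res.stderr * 10),
        mean=mean,
        std=float(vals.std(ddof=1)),
        net_percent_change=float(100.0 * res.slope * span / mean) if mean != 0 else np.nan,
        n_years=int(years.size),
    )


def below_mld_fraction(
    npp_total: xr.DataArray,
    npp_below: xr.DataArray,
    areas: xr.DataArray,
    mask: xr.DataArray | np.ndarray | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Fraction of global NPP occurring beneath the mixed layer.

    fraction(t) = global integral of NPP_below / global integral of NPP_total
    over cells where both are valid; months with zero total are NaN.  Returns
    (monthly fraction, calendar-year fraction from annually summed integrals).
    """
    time = pd.DatetimeIndex(npp_total.time.values)
    days = _days_in_months(time)
    w = areas.values.astype(float)
    if mask is not None:
        m = mask.values if isinstance(mask, xr.DataArray) else np.asarray(mask)
        w = w * m.astype(float)
    tot_v, bel_v = npp_total.values, npp_below.values
    both = np.isfinite(tot_v) & np.isfinite(bel_v)
    tot_int = np.array([(w * np.where(both[i], tot_v[i], 0.0)).sum() * days[i]
                        for i in range(time.size)])
    bel_int = np.array([(w * np.where(both[i], bel_v[i], 0.0)).sum() * days[i]
                        for i in range(time.size)])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot_int > 0, bel_int / np.where(tot_int > 0, tot_int, 1), np.nan)
    monthly = pd.Series(frac, index=time, name="below_mld_fraction")
    ann_tot = pd.Series(tot_int, index=time).groupby(time.year).sum()
    ann_bel = pd.Series(bel_int, index=time).groupby(time.year).sum()
    annual = (ann_bel / ann_tot.where(ann_tot > 0)).rename("below_mld_fraction")
    return monthly, annual
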