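"""Inter-mission comparison and climatology-difference blending.

Two ocean-color missions observing the same ocean carry small but persistent
relative biases.  Over their overlap we (1) quantify agreement on collocated
cell-months (correlation, Type-1 ordinary least-squares slope, and a
multiplicative mean absolute error), and (2) harmonize the earlier mission to
the later one by adding, per cell and calendar month, the mean overlap
difference (reference minus earlier).  The harmonized earlier mission and the
reference are then averaged where both exist and concatenated elsewhere.

A stationary per-calendar-month bias is removed exactly by this adjustment
when the overlap is noise-free, because the adjustment *is* the per-month
mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .exceptions import InsufficientDataError, NPPTrendsError

__all__ = [
    "ComparisonStats",
    "BlendAdjustment",
    "collocated_stats",
    "fit_adjustment",
    "apply_and_merge",
]

#: Minimum overlap observations per calendar month per cell for an adjustment.
MIN_OVERLAP_OBS = 3


@dataclass
class ComparisonStats:
    """Collocated agreement between two missions.

    ``mae_factor`` is the multiplicative mean absolute error,
    10**mean(|log10(a/b)|): dimensionless, >= 1, symmetric in a and b.
    """

    r: float
    slope: float
    intercept: float
    mae_factor: float
    n: int
    n_excluded_nonpositive: int = 0
    log_space: bool = True


@dataclass
class BlendAdjustment:
    """12 per-calendar-month difference fields (reference minus adjusted
    mission), missing where the overlap support is below the minimum."""

    diffs: xr.DataArray   # dims (month, lat, lon)
    counts: xr.DataArray  # overlap observations behind each difference

    def month(self, m: int) -> xr.DataArray:
        return self.diffs.sel(month=m)


def _collocated_pairs(a: xr.DataArray, b: xr.DataArray) -> tuple[np.ndarray, np.ndarray]:
    common = np.intersect1d(a.time.values, b.time.values)
    if common.size == 0:
        raise InsufficientDataError("missions share no months")
    av = a.sel(time=common).values.ravel()
    bv = b.sel(time=common).values.ravel()
    ok = np.isfinite(av) & np.isfinite(bv)
    return av[ok], bv[ok]


def collocated_stats(a: xr.DataArray, b: xr.DataArray,
                     log_space: bool = True) -> ComparisonStats:
    """Pearson r, Type-1 OLS slope, and multiplicative MAE on collocated pairs.

    With ``log_space`` (appropriate for strictly positive, log-normal-like
    quantities such as NPP) r and the slope are computed on log10-transformed
    pairs and non-positive values are excluded (their count is reported).  In
    linear space the MAE factor is still computed from the pairs where both
    values are positive.
    """
    av, bv = _collocated_pairs(a, b)
    n_excl = 0
    if log_space:
        pos = (av > 0) & (bv > 0)
        n_excl = int((~pos).sum())
        av, bv = av[pos], bv[pos]
        x, y = np.log10(av), np.log10(bv)
    else:
        x, y = av, bv
    if x.size < 3:
        raise InsufficientDataError(f"only {x.size} collocated pairs; need >= 3")
    res = stats.linregress(x, y)
    pos = (av > 0) & (bv > 0)
    mae = float(10 ** np.mean(np.abs(np.log10(av[pos] / bv[pos])))) if pos.any() else np.nan
    return ComparisonStats(
        r=float(res.rvalue), slope=float(res.slope), intercept=float(res.intercept),
        mae_factor=mae, n=int(x.size), n_excluded_nonpositive=n_excl,
        log_space=log_space,
    )


def fit_adjustment(a: xr.DataArray, b: xr.DataArray,
                   min_obs: int = MIN_OVERLAP_OBS) -> BlendAdjustment:
    """Per-cell, per-calendar-month mean of (b - a) over the overlap.

    b is the reference mission; a is the mission to be adjusted.  Cells with
    fewer than ``min_obs`` joint observations of a calendar month are left
    missing for that month.
    """
    common = np.intersect1d(a.time.values, b.time.values)
    if common.size == 0:
        raise InsufficientDataError("missions share no overlap months")
    diff = b.sel(time=common) - a.sel(time=common)
    months = xr.DataArray(pd.DatetimeIndex(common).month, dims="time",
                          coords={"time": common}, name="month")
    means = diff.groupby(months).mean("time", skipna=True)
    counts = np.isfinite(diff).groupby(months).sum("time")
    means = means.where(counts >= min_obs)
    means = means.reindex(month=np.arange(1, 13))
    counts = counts.reindex(month=np.arange(1, 13), fill_value=0)
    means.attrs["units"] = a.attrs.get("units", "")
    return BlendAdjustment(diffs=means, counts=counts)


def apply_and_merge(a: xr.DataArray, b: xr.DataArray,
                    adj: BlendAdjustment) -> xr.DataArray:
    """Adjust mission a by the per-month differences and merge with b.

    Output: a* = a + adj(month); a* where only a observes, b where only b
    observes, mean(a*, b) where both do.  Where the adjustment is undefined
    at an observed a cell-month, a is used unadjusted and the fallback count
    is recorded in ``attrs['n_unadjusted']``.
    """
    if not (np.array_equal(a.lat.values, b.lat.values)
            and np.array_equal(a.lon.values, b.lon.values)):
        raise NPPTrendsError("mission grids differ")
    months = pd.DatetimeIndex(a.time.values).month
    adj_at_t = adj.diffs.sel(month=xr.DataArray(months, dims="time")).values
    a_vals = a.values
    adj_filled = np.where(np.isfinite(adj_at_t), adj_at_t, 0.0)
    n_unadjusted = int((np.isfinite(a_vals) & ~np.isfinite(adj_at_t)).sum())
    a_star = a.copy(deep=True)
    a_star.values = a_vals + adj_filled

    all_times = np.union1d(a.time.values, b.time.values)
    a_full = a_star.reindex(time=all_times)
    b_full = b.reindex(time=all_times)
    stacked = np.stack([a_full.values, b_full.values])
    with np.errstate(invalid="ignore"):
        merged_vals = np.where(
            np.isfinite(stacked).any(axis=0),
            np.nansum(np.where(np.isfinite(stacked), stacked, 0.0), axis=0)
            / np.maximum(np.isfinite(stacked).sum(axis=0), 1),
            np.nan,
        )
    merged = xr.DataArray(
        merged_vals, dims=("time", "lat", "lon"),
        coords={"time": all_times, "lat": a.lat, "lon": a.lon},
        attrs=dict(a.attrs), name=a.name or "merged",
    )
    merged.attrs["n_unadjusted"] = n_unadjusted
    return merged
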