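"""Climatologies, anomalies, and autocorrelation-corrected trend estimation.

The per-pixel trend model is ordinary least squares on deseasonalized monthly
anomalies against time in decimal years.  Monthly anomalies are serially
correlated, so classical OLS understates the slope uncertainty; we quantify
lag-1 autocorrelation rho of the regression residuals and shrink the sample
count to an effective size

    n_eff = n * (1 - rho) / (1 + rho)        (capped at n when rho < 0)

then rescale the slope standard error by sqrt(n / n_eff) and test the slope
against a two-tailed Student-t interval with df = n_eff - 2.  Significance is
reported at the 90% level (alpha = 0.10) by default.  Slopes are reported per
decade; normalized trends divide the decadal slope by a reference-period mean
of the raw field and are expressed in percent per decade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .exceptions import EmptyDomainError, InsufficientDataError

__all__ = [
    "ClimatologySet",
    "monthly_climatology",
    "deseasonalize",
    "decimal_years",
    "ar1_effective_n",
    "trend_fit",
    "normalized_trend",
    "significant_area_fractions",
    "sst_bin_summary",
    "overlap_fraction",
    "weighted_quantile",
]

#: Default minimum valid anomalies per cell for trend testing.
MIN_MONTHS = 60
#: Default minimum observations per calendar month for a climatology value.
MIN_COUNT = 5


@dataclass
class ClimatologySet:
    """Per-calendar-month mean fields with valid-observation counts."""

    means: xr.DataArray   # dims (month, lat, lon), month = 1..12
    counts: xr.DataArray  # same dims, integer

    def month(self, m: int) -> xr.DataArray:
        return self.means.sel(month=m)


def _window_slice(series: xr.DataArray, window: tuple | None) -> xr.DataArray:
    if window is None:
        return series
    start, stop = window
    return series.sel(time=slice(str(start), str(stop)))


def monthly_climatology(
    series: xr.DataArray,
    window: tuple | None = None,
    min_count: int = MIN_COUNT,
) -> ClimatologySet:
    """Per-cell, per-calendar-month mean over valid observations in ``window``.

    Cells with fewer than ``min_count`` valid observations of a calendar month
    are left missing for that month.
    """
    sub = _window_slice(series, window)
    if sub.time.size == 0:
        raise EmptyDomainError("climatology window contains no data")
    months = sub.time.dt.month
    grouped = sub.groupby(months.rename("month"))
    means = grouped.mean("time", skipna=True)
    counts = np.isfinite(sub).groupby(months.rename("month")).sum("time")
    means = means.where(counts >= min_count)
    means = means.reindex(month=np.arange(1, 13))
    counts = counts.reindex(month=np.arange(1, 13), fill_value=0)
    means.attrs = dict(series.attrs)
    return ClimatologySet(means=means, counts=counts)


def deseasonalize(series: xr.DataArray, clim: ClimatologySet) -> xr.DataArray:
    """Anomaly = value - climatology(calendar month); missing propagates."""
    months = series.time.dt.month
    clim_at_t = clim.means.sel(month=months).drop_vars("month")
    anom = series - clim_at_t
    anom.attrs = dict(series.attrs)
    anom.attrs["long_name"] = "deseasonalized anomaly"
    return anom


def decimal_years(time: pd.DatetimeIndex | xr.DataArray) -> np.ndarray:
    """Decimal year at month centers: year + (month - 0.5)/12."""
    t = pd.DatetimeIndex(np.asarray(time))
    return t.year.values + (t.month.values - 0.5) / 12.0


def ar1_effective_n(residuals: np.ndarray) -> tuple[float, float]:
    """Lag-1 autocorrelation of a residual series and the effective sample size.

    rho is the Pearson correlation of consecutive residual pairs; n_eff is
    n(1-rho)/(1+rho), capped at n (negative rho is not allowed to inflate the
    sample).  Requires at least 10 finite residuals.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    n = r.size
    if n < 10:
        raise InsufficientDataError(f"need >= 10 residuals, got {n}")
    a, b = r[:-1], r[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        rho = 0.0
    else:
        rho = float(np.corrcoef(a, b)[0, 1])
    rho_pos = max(rho, 0.0)
    n_eff = n * (1.0 - rho_pos) / (1.0 + rho_pos)
    return rho, float(min(n_eff, n))


def trend_fit(
    anoms: xr.DataArray,
    min_months: int = MIN_MONTHS,
    alpha: float = 0.10,
    ar1_correction: bool = True,
) -> xr.Dataset:
    """Per-cell OLS trend of anomalies vs time with AR(1)-adjusted inference.

    Returns a Dataset with variables ``slope`` (units/decade), ``intercept``,
    ``rho``, ``n``, ``n_eff``, ``se_adj`` (units/decade), ``ci90_halfwidth``
    (units/decade at the configured alpha), and boolean ``significant``.
    Cells with fewer than ``min_months`` valid anomalies, or with
    n_eff - 2 < 2, are reported missing and counted in
    ``attrs['n_untestable']``.  Setting ``ar1_correction=False`` skips the
    effective-sample-size adjustment (classical OLS inference), which is only
    appropriate for serially independent residuals.
    """
    t = decimal_years(anoms.time)
    y = anoms.values  # (T, ...)
    valid = np.isfinite(y)
    n = valid.sum(axis=0).astype(float)
    testable = n >= max(min_months, 4)

    with np.errstate(invalid="ignore", divide="ignore"):
        tsum = (t[:, None, None] * valid).sum(axis=0)
        tbar = np.where(n > 0, tsum / np.where(n > 0, n, 1), np.nan)
        y0 = np.where(valid, y, 0.0)
        ybar = np.where(n > 0, y0.sum(axis=0) / np.where(n > 0, n, 1), np.nan)
        dt = np.where(valid, t[:, None, None] - tbar[None, ...], 0.0)
        dy = np.where(valid, y0 - ybar[None, ...], 0.0)
        sxx = (dt * dt).sum(axis=0)
        sxy = (dt * dy).sum(axis=0)
        slope_yr = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1), np.nan)
        intercept = ybar - slope_yr * tbar

        resid = np.where(valid, y0 - (intercept[None, ...] + slope_yr[None, ...] * t[:, None, None]), np.nan)

        # lag-1 Pearson autocorrelation of residuals, per cell
        a, b = resid[:-1], resid[1:]
        pair = np.isfinite(a) & np.isfinite(b)
        m = pair.sum(axis=0).astype(float)
        a0 = np.where(pair, a, 0.0)
        b0 = np.where(pair, b, 0.0)
        ma = np.where(m > 0, a0.sum(axis=0) / np.where(m > 0, m, 1), 0.0)
        mb = np.where(m > 0, b0.sum(axis=0) / np.where(m > 0, m, 1), 0.0)
        da = np.where(pair, a0 - ma, 0.0)
        db = np.where(pair, b0 - mb, 0.0)
        va = (da * da).sum(axis=0)
        vb = (db * db).sum(axis=0)
        cov = (da * db).sum(axis=0)
        denom = np.sqrt(va * vb)
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1), 0.0)
        rho = np.clip(rho, -1.0, 1.0 - 1e-12)

        if ar1_correction:
            rho_pos = np.clip(rho, 0.0, None)
            n_eff = n * (1.0 - rho_pos) / (1.0 + rho_pos)
        else:
            n_eff = n.copy()

        ss_res = np.nansum(resid**2, axis=0)
        s2 = np.where(n > 2, ss_res / np.where(n > 2, n - 2, 1), np.nan)
        se = np.sqrt(np.where(sxx > 0, s2 / np.where(sxx > 0, sxx, 1), np.nan))
        se_adj = se * np.sqrt(np.where(n_eff > 0, n / np.where(n_eff > 0, n_eff, 1), np.nan))

        df = n_eff - 2.0
        testable = testable & (df >= 2.0)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, np.where(df >= 2, df, 2))
        ci = tcrit * se_adj

    # per-decade reporting
    slope_dec = slope_yr * 10.0
    se_dec = se_adj * 10.0
    ci_dec = ci * 10.0
    sig = np.abs(slope_dec) > ci_dec

    def wrap(arr, units=""):
        da = xr.DataArray(
            np.where(testable, arr, np.nan),
            dims=("lat", "lon"),
            coords={"lat": anoms.lat, "lon": anoms.lon},
        )
        if units:
            da.attrs["units"] = units
        return da

    unit = anoms.attrs.get("units", "")
    per_dec = f"{unit}/decade" if unit else "per decade"
    ds = xr.Dataset(
        {
            "slope": wrap(slope_dec, per_dec),
            "intercept": wrap(intercept, unit),
            "rho": wrap(rho),
            "n": wrap(n),
            "n_eff": wrap(n_eff),
            "se_adj": wrap(se_dec, per_dec),
            "ci90_halfwidth": wrap(ci_dec, per_dec),
            "significant": xr.DataArray(
                np.where(testable, sig, False).astype(bool),
                dims=("lat", "lon"),
                coords={"lat": anoms.lat, "lon": anoms.lon},
            ),
        }
    )
    ds["testable"] = xr.DataArray(
        testable, dims=("lat", "lon"), coords={"lat": anoms.lat, "lon": anoms.lon}
    )
    ds.attrs["alpha"] = alpha
    ds.attrs["n_untestable"] = int((~testable).sum())
    ds.attrs["ar1_correction"] = int(ar1_correction)
    return ds


def fit_trend_1d(y: np.ndarray, t: np.ndarray, alpha: float = 0.10,
                 ar1_correction: bool = True) -> dict:
    """Single-series version of :func:`trend_fit` (slope per decade).

    Convenience wrapper used for global time series and Monte-Carlo checks.
    """
    da = xr.DataArray(
        np.asarray(y, dtype=float)[:, None, None],
        dims=("time", "lat", "lon"),
        coords={"time": pd.DatetimeIndex(t) if not np.issubdtype(np.asarray(t).dtype, np.number) else _fake_time(t),
                "lat": [0.0], "lon": [0.0]},
    )
    ds = trend_fit(da, min_months=4, alpha=alpha, ar1_correction=ar1_correction)
    return {k: float(ds[k].values[0, 0]) for k in
            ("slope", "intercept", "rho", "n", "n_eff", "se_adj", "ci90_halfwidth")} | {
        "significant": bool(ds["significant"].values[0, 0])}


def _fake_time(t_years: np.ndarray) -> pd.DatetimeIndex:
    """Monthly datetime axis whose decimal years equal ``t_years`` (must be
    consecutive month centers)."""
    t = np.asarray(t_years, dtype=float)
    years = np.floor(t).astype(int)
    months = np.clip(np.round(12 * (t - years) + 0.5).astype(int), 1, 12)
    return pd.DatetimeIndex([pd.Timestamp(y, m, 15) for y, m in zip(years, months)])


def normalized_trend(
    trends: xr.Dataset,
    raw_series: xr.DataArray,
    mean_ref_window: tuple = (1998, 2022),
    eps: float = 1e-12,
) -> xr.Dataset:
    """Add ``mean_ref`` and ``normalized_slope`` (%/decade) to a trend Dataset.

    mean_ref is the time mean of the raw (not anomaly) series over the
    reference window.  Cells with |mean_ref| < eps * scale are reported
    missing and counted in ``attrs['n_zero_mean']``.
    """
    sub = _window_slice(raw_series, mean_ref_window)
    mean_ref = sub.mean("time", skipna=True)
    scale = float(np.nanmax(np.abs(mean_ref.values))) if np.isfinite(mean_ref.values).any() else 1.0
    ok = np.abs(mean_ref) > eps * max(scale, 1.0)
    norm = 100.0 * trends["slope"] / mean_ref.where(ok)
    out = trends.copy()
    out["mean_ref"] = mean_ref
    out["normalized_slope"] = norm
    out["normalized_slope"].attrs["units"] = "%/decade"
    out.attrs["n_zero_mean"] = int((~ok & np.isfinite(trends["slope"].values)).sum())
    return out


def significant_area_fractions(
    trends: xr.Dataset,
    areas: xr.DataArray,
    mask: xr.DataArray | None = None,
) -> dict:
    """Area-weighted shares and mean rates of significant trends.

    Fractions are relative to the tested ocean area (cells with a valid trend
    estimate).  Mean rates are area-weighted means of the decadal slope (and,
    when present, the normalized slope) over each significant class.
    """
    w = areas.values.astype(float)
    if mask is not None:
        w = w * mask.values.astype(float)
    slope = trends["slope"].values
    sig = trends["significant"].values & np.isfinite(slope)
    tested = np.isfinite(slope) & (w > 0)
    total = (w * tested).sum()
    if total <= 0:
        raise EmptyDomainError("no tested ocean area")
    neg = sig & (slope < 0)
    pos = sig & (slope > 0)

    def wmean(field, sel):
        wt = (w * sel).sum()
        return float((w * np.where(sel, field, 0.0)).sum() / wt) if wt > 0 else np.nan

    out = {
        "frac_sig_neg": float((w * neg).sum() / total),
        "frac_sig_pos": float((w * pos).sum() / total),
        "mean_rate_neg": wmean(slope, neg),
        "mean_rate_pos": wmean(slope, pos),
        "tested_area_m2": float(total),
    }
    if "normalized_slope" in trends:
        ns = trends["normalized_slope"].values
        out["mean_norm_neg"] = wmean(np.where(np.isfinite(ns), ns, 0.0), neg & np.isfinite(ns))
        out["mean_norm_pos"] = wmean(np.where(np.isfinite(ns), ns, 0.0), pos & np.isfinite(ns))
    return out


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Weighted quantiles by linear interpolation of the weighted CDF
    evaluated at the midpoints of each observation's weight mass."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(v) & (w > 0)
    v, w = v[ok], w[ok]
    if v.size == 0:
        return np.full(np.shape(q), np.nan)
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.asarray(q, dtype=float), cw, v)


def sst_bin_summary(
    trends: xr.Dataset,
    sst_mean: xr.DataArray,
    areas: xr.DataArray,
    mask: xr.DataArray | None = None,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Trend distribution and significant-area fractions in mean-SST bins.

    Cells are assigned to ``bin_width``-degree bins of the reference-period
    mean SST.  Per bin: area-weighted 10/25/50/75/90th trend percentiles, the
    areal fraction of significant positive / negative trends relative to bin
    area, and total bin area.  Empty bins report zero area and NaN percentiles.
    """
    w = areas.values.astype(float)
    if mask is not None:
        w = w * mask.values.astype(float)
    slope = trends["slope"].values
    sig = trends["significant"].values
    sstv = sst_mean.values
    tested = np.isfinite(slope) & np.isfinite(sstv) & (w > 0)

    lo = np.floor(np.nanmin(np.where(tested, sstv, np.nan)) / bin_width) * bin_width
    hi = np.ceil(np.nanmax(np.where(tested, sstv, np.nan)) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)

    rows = []
    for i in range(edges.size - 1):
        inbin = tested & (sstv >= edges[i]) & (sstv < edges[i + 1])
        area = float((w * inbin).sum())
        row = {"sst_lo": edges[i], "sst_hi": edges[i + 1], "area_m2": area}
        if area > 0:
            qs = weighted_quantile(slope[inbin], w[inbin], [0.10, 0.25, 0.50, 0.75, 0.90])
            row.update(dict(zip(["p10", "p25", "p50", "p75", "p90"], map(float, qs))))
            row["frac_sig_pos"] = float((w * (inbin & sig & (slope > 0))).sum() / area)
            row["frac_sig_neg"] = float((w * (inbin & sig & (slope < 0))).sum() / area)
        else:
            row.update({k: np.nan for k in ["p10", "p25", "p50", "p75", "p90",
                                            "frac_sig_pos", "frac_sig_neg"]})
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_fraction(
    mask_a: xr.DataArray | np.ndarray,
    mask_b: xr.DataArray | np.ndarray,
    areas: xr.DataArray,
) -> float:
    """Percent of mask_a's area also covered by mask_b: 100 * area(a&b)/area(a)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    w = areas.values.astype(float)
    area_a = (w * a).sum()
    if area_a <= 0:
        raise EmptyDomainError("mask_a covers zero area")
    return float(100.0 * (w * (a & b)).sum() / area_a)
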