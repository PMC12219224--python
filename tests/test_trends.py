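"""Climatology, deseasonalization, AR(1)-corrected trend inference, and
area-weighted summaries."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from npptrends.exceptions import EmptyDomainError, InsufficientDataError
from npptrends.grid import GeoGrid, cell_areas
from npptrends.synthetic import generate_field, month_axis
from npptrends.trends import (ar1_effective_n, decimal_years, deseasonalize,
                              monthly_climatology, normalized_trend,
                              overlap_fraction, significant_area_fractions,
                              sst_bin_summary, trend_fit, weighted_quantile)
from tests.conftest import make_series


def sc(da):
    """Scalar value of a single-cell result field."""
    return float(np.asarray(da.values).reshape(-1)[0])


def single_cell(values, start="2000-01"):
    return make_series(np.asarray(values, dtype=float)[:, None, None],
                       start=start, lat=[0.0], lon=[0.0])


class TestClimatology:
    def test_constant_series(self):
        s = single_cell(np.full(60, 4.5))
        clim = monthly_climatology(s)
        np.testing.assert_allclose(clim.means.values, 4.5)

    def test_exact_annual_sinusoid_reproduced(self):
        t = np.arange(120)
        vals = 10 + 3 * np.cos(2 * np.pi * (t % 12) / 12)
        s = single_cell(vals)
        clim = monthly_climatology(s)
        np.testing.assert_allclose(clim.means.values.ravel(), vals[:12], rtol=1e-12)

    def test_min_count_leaves_month_missing(self):
        vals = np.full(48, np.nan)
        vals[[0, 12, 24]] = 1.0  # three Januaries only
        s = single_cell(vals)
        clim = monthly_climatology(s, min_count=5)
        assert np.isnan(clim.means.sel(month=1).values[0, 0])
        assert clim.counts.sel(month=1).values[0, 0] == 3

    def test_window_restricts_the_mean(self):
        vals = np.concatenate([np.full(24, 1.0), np.full(24, 3.0)])
        s = single_cell(vals, start="2000-01")
        clim = monthly_climatology(s, window=(2002, 2003), min_count=2)
        np.testing.assert_allclose(clim.means.values, 3.0)


class TestDeseasonalize:
    def test_series_equal_to_climatology_gives_zero(self):
        vals = np.tile(np.arange(12, dtype=float), 5) + 7
        s = single_cell(vals)
        anoms = deseasonalize(s, monthly_climatology(s))
        np.testing.assert_allclose(anoms.values, 0.0, atol=1e-12)

    def test_monthly_anomaly_means_vanish(self):
        rng = np.random.default_rng(8)
        s = make_series(rng.normal(100, 10, (120, 6, 6)))
        anoms = deseasonalize(s, monthly_climatology(s))
        for m in range(1, 13):
            sel = anoms.sel(time=anoms.time.dt.month == m)
            np.testing.assert_allclose(sel.mean("time").values, 0.0, atol=1e-10)

    def test_trend_survives_seasonal_power_removed(self):
        """Planted trend + strong seasonal cycle: anomalies keep the trend and
        lose >99% of the annual-harmonic power."""
        grid = GeoGrid.regular(30.0)
        s = generate_field(grid, n_months=240, seasonal_amplitude=100.0,
                           trend_per_decade=-50.0, rho=0.0, innovation_sd=1.0,
                           seed=2)
        anoms = deseasonalize(s, monthly_climatology(s))
        cell_raw = s.values[:, 1, 1]
        cell_anom = anoms.values[:, 1, 1]

        def annual_power(x):
            f = np.fft.rfft(x - np.polyval(np.polyfit(np.arange(x.size), x, 1),
                                           np.arange(x.size)))
            freqs = np.fft.rfftfreq(x.size)
            band = np.abs(freqs - 1 / 12) < 0.01
            return (np.abs(f[band]) ** 2).sum()

        assert annual_power(cell_anom) < 0.01 * annual_power(cell_raw)
        slope = np.polyfit(np.arange(240) / 120.0, cell_anom, 1)[0]
        assert slope == pytest.approx(-50.0, abs=5.0)


class TestAR1EffectiveN:
    def test_closed_form(self):
        """rho = 0.5, n = 303 -> n_eff = 303 * (0.5/1.5) = 101."""
        rng = np.random.default_rng(0)
        # build residuals with exactly rho = 0.5 empirical lag-1 correlation
        # via the formula directly: feed a synthetic series and check formula
        r = np.zeros(303)
        r[0] = rng.normal()
        for i in range(1, 303):
            r[i] = 0.5 * r[i - 1] + rng.normal()
        rho, n_eff = ar1_effective_n(r)
        assert n_eff == pytest.approx(303 * (1 - rho) / (1 + rho), rel=1e-12)
        # the exact closed-form value for rho = 0.5:
        assert 303 * (1 - 0.5) / (1 + 0.5) == pytest.approx(101.0)

    def test_negative_rho_capped_at_n(self):
        r = np.array([1.0, -1.0] * 10)
        rho, n_eff = ar1_effective_n(r)
        assert rho < 0
        assert n_eff == 20

    def test_white_noise_rho_near_zero(self):
        rng = np.random.default_rng(1)
        n = 300
        hits = 0
        for _ in range(500):
            rho, n_eff = ar1_effective_n(rng.normal(size=n))
            if abs(rho) < 2 / np.sqrt(n):
                hits += 1
        assert hits >= 0.90 * 500

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            ar1_effective_n(np.arange(5.0))


class TestTrendFit:
    def test_exact_line_recovered_and_significant(self):
        t = month_axis("2000-01", 120)
        ty = decimal_years(t)
        vals = 3.0 * (ty - ty[0]) / 10.0  # 3 units per decade
        s = single_cell(vals)
        ds = trend_fit(s, min_months=60)
        assert sc(ds.slope) == pytest.approx(3.0, rel=1e-10)
        assert bool(sc(ds.significant))

    def test_constant_series_zero_slope_not_significant(self):
        s = single_cell(np.full(120, 2.0))
        ds = trend_fit(s, min_months=60)
        assert sc(ds.slope) == pytest.approx(0.0, abs=1e-12)
        assert not bool(sc(ds.significant))

    def test_slope_matches_brute_force_oracle(self):
        """Vectorized slope equals the closed-form OLS slope computed
        independently, to 1e-10, on random gappy series."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(70, 200))
            vals = rng.normal(0, 5, n)
            vals[rng.random(n) < 0.2] = np.nan
            s = single_cell(vals)
            ds = trend_fit(s, min_months=30)
            ty = decimal_years(s.time)
            ok = np.isfinite(vals)
            tt, yy = ty[ok], vals[ok]
            expected = (((tt - tt.mean()) * (yy - yy.mean())).sum()
                        / ((tt - tt.mean()) ** 2).sum()) * 10
            assert sc(ds.slope) == pytest.approx(expected, abs=1e-10 * max(1, abs(expected)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_slope_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 2, 80)
        s = single_cell(vals)
        ds = trend_fit(s, min_months=60)
        ty = decimal_years(s.time)
        expected = np.polyfit(ty, vals, 1)[0] * 10
        assert sc(ds.slope) == pytest.approx(expected, abs=1e-8)

    def test_rho_zero_recovers_classical_inference(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=150)
        s = single_cell(vals)
        with_corr = trend_fit(s, min_months=60, ar1_correction=True)
        without = trend_fit(s, min_months=60, ar1_correction=False)
        # same slope; adjusted SE differs only through the estimated rho
        assert sc(with_corr.slope) == sc(without.slope)
        assert sc(with_corr.n_eff) <= sc(with_corr.n)
        if sc(with_corr.rho) <= 0:
            assert sc(with_corr.se_adj) == pytest.approx(sc(without.se_adj))

    def test_short_series_untestable(self):
        vals = np.full(120, np.nan)
        vals[:30] = np.arange(30.0)
        s = single_cell(vals)
        ds = trend_fit(s, min_months=60)
        assert np.isnan(sc(ds.slope))
        assert ds.attrs["n_untestable"] == 1

    def test_null_coverage_small(self):
        """Under an AR(1) null the 90% flag should fire at roughly 10%; a
        coarse check at 300 replicate cells (the full-power version of this
        experiment runs in the acceptance suite)."""
        rng = np.random.default_rng(5)
        n, ncell, rho = 300, 300, 0.6
        y = np.empty((n, ncell))
        y[0] = rng.normal(0, 1 / np.sqrt(1 - rho**2), ncell)
        for t in range(1, n):
            y[t] = rho * y[t - 1] + rng.normal(0, 1, ncell)
        s = make_series(y[:, :, None], lat=np.arange(ncell, dtype=float) / 10,
                        lon=[0.0])
        ds = trend_fit(s, min_months=60)
        rate = ds.significant.values.mean()
        assert 0.04 < rate < 0.17


class TestNormalizedTrend:
    def test_percent_per_decade(self):
        vals = np.full(300, 100.0)
        s = single_cell(vals, start="1998-01")
        ds = trend_fit(s, min_months=60)
        ds["slope"].values[:] = 10.0
        out = normalized_trend(ds, s, (1998, 2022))
        assert sc(out.normalized_slope) == pytest.approx(10.0)

    def test_ocean_scale_arithmetic(self):
        """Slope -34 mg C m-2 d-1 per decade on a ~479 mg C m-2 d-1 mean
        field normalizes to -7.1 %/decade."""
        vals = np.full(300, 479.0)
        s = single_cell(vals, start="1998-01")
        ds = trend_fit(s, min_months=60)
        ds["slope"].values[:] = -34.0
        out = normalized_trend(ds, s, (1998, 2022))
        assert sc(out.normalized_slope) == pytest.approx(-7.1, abs=0.01)

    def test_zero_mean_reported_missing(self):
        vals = np.zeros(300)
        s = single_cell(vals, start="1998-01")
        ds = trend_fit(s, min_months=60)
        out = normalized_trend(ds, s, (1998, 2022))
        assert np.isnan(sc(out.normalized_slope))


class TestAreaFractions:
    def _toy_trends(self, slopes, sig):
        slopes = np.asarray(slopes, dtype=float)[None, :]
        sig = np.asarray(sig, dtype=bool)[None, :]
        coords = {"lat": [0.0], "lon": np.arange(slopes.shape[1], dtype=float)}
        return xr.Dataset({
            "slope": xr.DataArray(slopes, dims=("lat", "lon"), coords=coords),
            "significant": xr.DataArray(sig, dims=("lat", "lon"), coords=coords),
        })

    def test_all_significant_negative(self):
        tr = self._toy_trends([-1, -2, -3], [True, True, True])
        areas = xr.DataArray([[1.0, 1.0, 1.0]], dims=("lat", "lon"),
                             coords={"lat": [0.0], "lon": [0.0, 1.0, 2.0]})
        out = significant_area_fractions(tr, areas)
        assert out["frac_sig_neg"] == pytest.approx(1.0)
        assert out["frac_sig_pos"] == 0.0

    def test_two_cell_area_weighting(self):
        """Areas 1 and 3, only the small cell significant: fraction 0.25."""
        tr = self._toy_trends([-1.0, 2.0], [True, False])
        areas = xr.DataArray([[1.0, 3.0]], dims=("lat", "lon"),
                             coords={"lat": [0.0], "lon": [0.0, 1.0]})
        out = significant_area_fractions(tr, areas)
        assert out["frac_sig_neg"] == pytest.approx(0.25)
        assert out["mean_rate_neg"] == pytest.approx(-1.0)

    def test_zero_tested_area_raises(self):
        tr = self._toy_trends([np.nan], [False])
        areas = xr.DataArray([[1.0]], dims=("lat", "lon"),
                             coords={"lat": [0.0], "lon": [0.0]})
        with pytest.raises(EmptyDomainError):
            significant_area_fractions(tr, areas)

    def test_fractions_use_area_not_counts(self):
        """Splitting every cell into two half-area cells with the same values
        leaves the fractions unchanged."""
        tr = self._toy_trends([-1.0, 2.0, 0.5], [True, True, False])
        areas = xr.DataArray([[2.0, 4.0, 6.0]], dims=("lat", "lon"),
                             coords={"lat": [0.0], "lon": [0.0, 1.0, 2.0]})
        out1 = significant_area_fractions(tr, areas)
        tr2 = self._toy_trends([-1.0, -1.0, 2.0, 2.0, 0.5, 0.5],
                               [True, True, True, True, False, False])
        areas2 = xr.DataArray([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]],
                              dims=("lat", "lon"),
                              coords={"lat": [0.0],
                                      "lon": np.arange(6, dtype=float)})
        out2 = significant_area_fractions(tr2, areas2)
        for key in ("frac_sig_neg", "frac_sig_pos", "mean_rate_neg", "mean_rate_pos"):
            assert out1[key] == pytest.approx(out2[key])


class TestOverlapFraction:
    areas = xr.DataArray([[1.0, 1.0, 1.0, 1.0]], dims=("lat", "lon"),
                         coords={"lat": [0.0], "lon": np.arange(4.0)})

    def test_identical_masks(self):
        m = np.array([[True, True, False, False]])
        assert overlap_fraction(m, m, self.areas) == pytest.approx(100.0)

    def test_disjoint_masks(self):
        a = np.array([[True, True, False, False]])
        b = np.array([[False, False, True, True]])
        assert overlap_fraction(a, b, self.areas) == 0.0

    def test_partial_overlap_two_thirds(self):
        a = np.array([[True, True, True, False]])
        b = np.array([[False, True, True, True]])
        assert overlap_fraction(a, b, self.areas) == pytest.approx(66.7, abs=0.05)

    def test_empty_reference_mask_raises(self):
        a = np.zeros((1, 4), dtype=bool)
        with pytest.raises(EmptyDomainError):
            overlap_fraction(a, a, self.areas)


class TestSSTBinSummary:
    def test_uniform_trend_collapses_percentiles(self):
        grid = GeoGrid.regular(10.0)
        areas = cell_areas(grid)
        coords = grid.coords()
        tr = xr.Dataset({
            "slope": xr.DataArray(np.full(grid.shape, -2.0), dims=("lat", "lon"),
                                  coords=coords),
            "significant": xr.DataArray(np.zeros(grid.shape, bool),
                                        dims=("lat", "lon"), coords=coords),
        })
        sst = xr.DataArray(np.full(grid.shape, 12.3), dims=("lat", "lon"),
                           coords=coords)
        table = sst_bin_summary(tr, sst, areas)
        row = table[table.area_m2 > 0].iloc[0]
        for q in ("p10", "p25", "p50", "p75", "p90"):
            assert row[q] == pytest.approx(-2.0)

    def test_step_across_isotherm_and_area_conservation(self):
        grid = GeoGrid.regular(10.0)
        areas = cell_areas(grid)
        coords = grid.coords()
        lat = np.broadcast_to(grid.lat_centers[:, None], grid.shape)
        sst_vals = 30.0 * np.cos(np.deg2rad(lat)) - 2.0
        slope = np.where(sst_vals < 15.0, 20.0, -30.0)
        tr = xr.Dataset({
            "slope": xr.DataArray(slope, dims=("lat", "lon"), coords=coords),
            "significant": xr.DataArray(slope < 0, dims=("lat", "lon"),
                                        coords=coords),
        })
        sst = xr.DataArray(sst_vals, dims=("lat", "lon"), coords=coords)
        table = sst_bin_summary(tr, sst, areas)
        cold = table[(table.sst_hi <= 15.0) & (table.area_m2 > 0)]
        warm = table[(table.sst_lo >= 15.0) & (table.area_m2 > 0)]
        assert np.allclose(cold.p50, 20.0)
        assert np.allclose(warm.p50, -30.0)
        assert np.allclose(cold.frac_sig_neg, 0.0)
        assert np.allclose(warm.frac_sig_neg, 1.0)
        assert table.area_m2.sum() == pytest.approx(float(areas.sum()), rel=1e-10)


class TestWeightedQuantile:
    def test_equal_weights_match_numpy(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=1001)
        w = np.ones_like(v)
        q = weighted_quantile(v, w, [0.25, 0.5, 0.75])
        expected = np.quantile(v, [0.25, 0.5, 0.75])
        np.testing.assert_allclose(q, expected, atol=0.02 * v.std())

    def test_weight_doubling_invariance(self):
        v = np.array([1.0, 2.0, 3.0, 10.0])
        w = np.array([1.0, 2.0, 1.0, 0.5])
        np.testing.assert_allclose(weighted_quantile(v, w, [0.1, 0.5, 0.9]),
                                   weighted_quantile(v, 2 * w, [0.1, 0.5, 0.9]))
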