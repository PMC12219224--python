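# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Data model

All gridded inputs are monthly fields on an equal-angle latitude/longitude
grid with cell-center registration (latitude −90…90, longitude −180…180),
carried as `xarray.DataArray` with dims `(time, lat, lon)`, a mandatory
`units` attribute, and NaN as the only missing-data representation (no
sentinel values; every reduction is written so that inserting missing cells
with arbitrary underlying values cannot change a result).  Time stamps are
calendar months at mid-month; regression time is decimal years at month
centers, year + (month − 0.5)/12.

Cell areas use a spherical Earth of radius R = 6371.0 km:
A = R² Δλ (sin φ₂ − sin φ₁).  At this precision the choice of ellipsoid is
irrelevant to area *weighting* (it cancels in every fraction and mean); only
absolute global integrals carry the ~0.1% level sensitivity, which is far
below the interannual variability of the quantities integrated.

## Mission blending

Two missions observing the same ocean are compared on collocated cell-months.
Agreement statistics are Pearson r and a Type-1 (ordinary least-squares)
regression slope, computed on log10-transformed pairs for strictly positive
log-normal-like quantities such as NPP, and a multiplicative mean absolute
error 10^mean(|log10(a/b)|) — dimensionless, ≥ 1, and symmetric in the two
missions.  The log-space convention is standard for ocean-color radiometric
products, whose errors are closer to multiplicative than additive.

Harmonization adds to the earlier mission, per cell and calendar month, the
mean overlap difference (reference − earlier), requiring at least 3 joint
observations of that calendar month per cell; the harmonized earlier mission
and the reference are averaged where both observe and concatenated elsewhere.
Differences (not ratios) are used; the later mission is the reference.  For
any *stationary* per-calendar-month bias and a noise-free overlap this
adjustment is exact by construction — the adjustment *is* the per-month mean
difference — which the tests verify to machine precision.  Where the
adjustment is undefined (insufficient overlap support, e.g. polar night) the
earlier mission passes through unadjusted and the count is reported.

## Trend inference

Trends are fitted to deseasonalized anomalies (value minus the per-cell,
per-calendar-month climatology; climatology values require at least 5
observations of that month).  Per cell:

1. OLS slope and intercept of anomaly against decimal years.
2. ρ = lag-1 Pearson autocorrelation of the regression residuals
   (consecutive valid months; gaps are treated as adjacent pairs removed).
3. Effective sample size n_eff = n (1 − ρ)/(1 + ρ), capped at n when ρ < 0
   (a negative estimated ρ is not allowed to *inflate* the information
   content — the conservative direction).
4. Slope standard error rescaled by √(n / n_eff); two-tailed Student-t
   interval with df = n_eff − 2 at α = 0.10 (90% confidence); a cell is
   "significant" when |slope| exceeds the interval half-width.
5. Slopes reported per decade; the normalized trend divides by the
   reference-period (default 1998–2022) mean of the *raw* series and is in
   % per decade, reported missing where that mean is ~0.

Cells with fewer than 60 valid anomalies, or with n_eff − 2 < 2, are
untestable and reported missing (counted in the output attributes).  Cells
with a constant series get slope 0, not significant.

Calibration: under a no-trend AR(1) null with ρ = 0.6 and n = 300 the 90%
flag fires at ≈ 11% of cells (Monte-Carlo mean over seeds ≈ 11.2%, per-run
spread ± ~0.7% at 2000 cells), against > 40% without the correction.  The
residual ~1-point excess over the nominal 10% traces to the downward
small-sample bias of residual-based ρ̂; we keep the plain estimator rather
than stacking bias corrections, and read the calibration as "nominal to
within Monte-Carlo tolerance", which the acceptance experiment quantifies
rather than hides.

Area summaries (significant-area fractions, mean rates over significant
classes, SST-bin percentiles) are always area-weighted, never cell-counted;
weighted percentiles interpolate the weighted CDF evaluated at the midpoint
of each observation's weight mass.  Mean-SST bins are 1 °C wide; empty bins
report zero area and no percentiles.

Out of scope by design: nonparametric (Theil–Sen / Mann–Kendall)
alternatives and field-significance or multiple-testing control across
pixels — the per-pixel 90% test is reported as such.

## EOF decomposition

Anomalies are first aggregated onto a near-equal-area grid: latitude bands of
fixed meridional extent, each split into longitude cells of matching zonal
extent (whole source cells assigned by center; no fractional splitting — at
production resolution ratios the sub-cell error is negligible).  A target
cell's area is the summed contributing source area, which makes the
aggregation conserve the global area-weighted mean of fully valid fields
exactly.  Cells with less than 80% temporal coverage are dropped; remaining
gaps are set to zero anomaly (the minimal-leverage value); columns are
re-centered (guarding against gap-induced offsets); each column is scaled by
√area so the SVD partitions area-weighted variance exactly even on the
only-approximately-equal-area grid.  Variance fractions are σᵢ²/Σσ² over the
full rank.  Modes are returned in anomaly units per unit PC (weights divided
back out).  Signs are arbitrary; each PC is oriented so its correlation with
time is non-negative.  PC–index correlations are plain Pearson on common
months (≥ 24 required), no smoothing or lagging; per mode the
largest-|r| index is flagged.  A mode's global NPP range integrates
pattern × area, scales by the PC, annualizes with 365.25 d yr⁻¹, converts
mg → Pg (10⁻¹⁸), and reports max − min.

## Budgets

Global monthly totals sum NPP × area × true calendar days-in-month over ocean
cells (mg C → Pg C via 10⁻¹⁸); annual totals sum complete calendar years.
Gap-filling with the monthly climatology is applied *only* for global totals,
and only where the climatological PAR exceeds 1 mol photons m⁻² d⁻¹ — the
sunlit domain, so cloud gaps are filled but polar night is not treated as
zero-observed production.  Climatological (not observed) PAR defines the
domain because observed PAR is missing exactly where filling is needed.  The
filled area fraction is recorded per month; fill-domain cells lacking a
climatology are counted and left unfilled.  The trend of annual totals is
classical OLS (annual means of monthly AR(1) noise at the ρ values relevant
here are nearly serially independent); the "net percent change" is defined as
slope × record span / record mean — one of several possible conventions
(fitted-endpoint ratios differ in the second digit) and stated with the
output.  The below-mixed-layer fraction is the ratio of global integrals of
NPP_z>MLD and total NPP over their common valid cells, monthly and annually.

The component identity NPP = PAR · (a_φ/a) · φ_μ and μ = NPP/C_phyto are
verified, not assumed: the residual statistic reports the maximum relative
residual over valid cells, and a nonzero value on real inputs would be
surfaced, not clipped.

## Synthetic generator

Each component field is climatology + trend + planted modes + AR(1) noise:

* climatology: latitude-dependent mean plus a seasonal harmonic whose
  amplitude grows as |sin(lat)| and whose phase flips by six months across
  the equator;
* trend: a per-cell slope in units per decade applied against time centered
  on the record midpoint (so the planted slope *is* the OLS-recoverable
  decadal trend); the pipeline's demo scenario flips the trend sign across a
  mean-SST isotherm (default 15 °C);
* AR(1) noise initialized from its stationary distribution
  (SD = innovation SD/√(1−ρ²)), avoiding burn-in transients that would bias
  trend tests;
* planted modes: separable loading × pattern(x) × index(t) terms for EOF
  recovery experiments.

NPP is constructed exactly as PAR × (a_φ/a) × φ_μ, μ as NPP/C_phyto, and the
below-MLD field as a clipped fraction (≤ 0.95) of NPP, so the identities hold
to machine precision and the below-MLD fraction is bounded by construction.
C_phyto is log-normal about a latitude-dependent mean (only the μ identity is
constrained by theory; no distributional claim is inherited from data).
Missingness is applied last: independent per-cell-month cloud gaps (default
5%) plus polar night wherever synthetic PAR < 1 mol photons m⁻² d⁻¹; SST and
MLD, which come from non-ocean-color sensors, stay complete.  A synthetic
land mask (two idealized continents, ~30% of the globe) keeps area-weighted
reductions honest.  Mission pairs share one underlying noise realization;
mission A adds a stationary per-calendar-month bias on its date range, and at
least 12 months of overlap are required (one full cycle of calendar months).

Default scale is a 2° × 2° grid (90 × 180) over 300 months (1998–2022, 25
complete calendar years); these sizes give the Monte-Carlo experiments
useful power while keeping a full run in tens of seconds.  Full-resolution
generation is supported but not the default.  Base magnitudes are chosen so
products land in observed ranges (NPP of a few hundred mg C m⁻² d⁻¹ from
PAR ~ tens of mol photons m⁻² d⁻¹, absorbed fraction ~ 0.05, carbon
efficiency ~ hundreds of mg C per mol photons; growth rates of a few tenths
per day).  Noise magnitudes are chosen for test power: real anomaly fields
have spatial covariance, non-Gaussian tails, and non-stationary missingness
that the generator does not emulate, so passing recovery tests demonstrates
the *correctness of the estimators under the stated stochastic model*, not
the detectability of any particular real-world trend.

## Pipeline

The orchestration layer is deliberately thin: stages (synth → blend → trends
→ eof → totals → report) communicate only through files in the run
directory, so any downstream stage rerun from cached outputs reproduces the
full-run results exactly, and a fixed config + seed reproduces every
numerical output byte-for-byte (wall-clock timings live in a separate file;
the frozen config copy embeds the run path).  Configuration is a single YAML
file validated before any compute; CLI flags override the config.  External
(non-synthetic) inputs enter through per-variable netCDF paths in the config
and flow through the identical stages.

## Known limitations

* The equal-area aggregation assigns whole source cells by center; at coarse
  desk-scale resolutions (source cells wider than target cells) target cells
  inherit single-cell values and their nominal geometry is only approximate —
  the summed-source-area bookkeeping keeps all weighted statistics exact
  regardless.
* The AR(1) model is first-order only; longer-memory processes would require
  a different effective-sample-size correction.
* EOF mode significance (North's rule etc.), rotated EOFs, and lagged index
  correlations are not implemented.
* netCDF output uses the NETCDF3 container (CF-style coordinates and
  attributes), which any CF-aware reader consumes.
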