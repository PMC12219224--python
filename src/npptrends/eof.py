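"""Empirical orthogonal function decomposition of anomaly fields.

Anomalies on the near-equal-area grid form a (time x cell) matrix X.  Cells
with less than a minimum temporal coverage are dropped; remaining gaps are
set to zero anomaly (the minimal-leverage value); columns are re-centered;
each column is scaled by sqrt(cell area) so the decomposition partitions
area-weighted variance exactly; then X_w = U S V^T by singular value
decomposition.  Mode i's principal component is U[:, i] * S[i] (unitless PC
amplitude times anomaly scale lives in the PC), its spatial pattern is
V[:, i] / sqrt(w) (anomaly units per unit PC), and its variance fraction is
S[i]^2 / sum(S^2).

Each mode's sign is arbitrary; we orient PCs so their correlation with time
is non-negative (a declining-field mode therefore appears as a negative
spatial pattern with a rising PC).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, UnitsError
from .grid import EqualAreaField

__all__ = [
    "EOFResult",
    "eof_decompose",
    "correlate_indices",
    "pc_npp_range",
]

#: Days per year used to annualize monthly global integrals.
DAYS_PER_YEAR = 365.25
#: mg C -> Pg C.
MG_TO_PG = 1e-18


@dataclass
class EOFResult:
    """Spatial modes, PCs, and variance fractions of an anomaly matrix."""

    modes: np.ndarray             # (k, ncell), anomaly units per unit PC
    pcs: np.ndarray               # (ntime, k), unit PC amplitude
    variance_fraction: np.ndarray  # (k,), of total (full-rank) variance
    singular_values: np.ndarray   # (k,)
    cell_area: np.ndarray         # (ncell,) m^2 of retained cells
    cell_lat: np.ndarray
    cell_lon: np.ndarray
    retained: np.ndarray          # boolean over the input field's cells
    time: pd.DatetimeIndex
    units: str

    @property
    def k(self) -> int:
        return self.pcs.shape[1]

    def reconstruct_weighted(self) -> np.ndarray:
        """Reconstruction of the centered, sqrt(area)-weighted matrix from
        the retained modes."""
        w = np.sqrt(self.cell_area)
        return (self.pcs @ (self.modes * w[None, :]))


def eof_decompose(
    field: EqualAreaField,
    k: int = 4,
    coverage_min: float = 0.8,
) -> EOFResult:
    """EOF decomposition of an equal-area anomaly field.

    Cells with temporal coverage below ``coverage_min`` are dropped; remaining
    gaps are zero-filled; columns are centered; sqrt(area) weighting makes the
    variance partition area-weighted.  ``k`` greater than the matrix rank is
    truncated with a warning.
    """
    X = np.asarray(field.values, dtype=float)
    if X.ndim != 2:
        raise InsufficientDataError("EOF needs a (time x cell) matrix")
    ntime = X.shape[0]
    coverage = np.isfinite(X).mean(axis=0)
    retained = coverage >= coverage_min
    if retained.sum() < 2:
        raise InsufficientDataError("fewer than 2 cells meet the coverage threshold")
    Xr = X[:, retained]
    Xr = np.where(np.isfinite(Xr), Xr, 0.0)
    Xr = Xr - Xr.mean(axis=0, keepdims=True)

    area = field.cell_area[retained]
    w = np.sqrt(area)
    Xw = Xr * w[None, :]

    U, S, Vt = np.linalg.svd(Xw, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size and S[0] > 0 else 0
    if k > rank:
        warnings.warn(f"requested {k} modes but rank is {rank}; truncating", stacklevel=2)
        k = max(rank, 1)

    total_var = float((S**2).sum())
    var_frac = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)

    pcs = U[:, :k] * S[:k][None, :]
    modes = Vt[:k, :] / w[None, :]

    # sign convention: corr(PC, time) >= 0; tie-break on the PC's largest element
    t = np.arange(ntime, dtype=float)
    for i in range(k):
        pc = pcs[:, i]
        c = np.corrcoef(pc, t)[0, 1] if pc.std() > 0 else 0.0
        flip = c < 0 or (c == 0 and pc[np.argmax(np.abs(pc))] < 0)
        if flip:
            pcs[:, i] = -pcs[:, i]
            modes[i] = -modes[i]

    return EOFResult(
        modes=modes, pcs=pcs, variance_fraction=np.asarray(var_frac),
        singular_values=S[:k], cell_area=area,
        cell_lat=field.grid.cell_lat[retained],
        cell_lon=field.grid.cell_lon[retained],
        retained=retained,
        time=field.time if field.time is not None else pd.DatetimeIndex([]),
        units=field.units,
    )


def full_variance_fractions(field: EqualAreaField, coverage_min: float = 0.8) -> np.ndarray:
    """Variance fractions of all modes (full rank); they sum to 1."""
    res = eof_decompose(field, k=10**9, coverage_min=coverage_min)
    return res.variance_fraction


def correlate_indices(
    result: EOFResult,
    indices: pd.DataFrame,
    min_months: int = 24,
) -> pd.DataFrame:
    """Pearson correlation of every PC against every climate index.

    ``indices``: DataFrame with a DatetimeIndex (monthly) and one column per
    index.  Pairs sharing fewer than ``min_months`` months are skipped with a
    warning.  Returns a table (mode, index, r, n, best) ranked per mode by
    |r|; the most-correlated index per mode has ``best=True``.
    """
    if not isinstance(indices.index, pd.DatetimeIndex):
        raise UnitsError("indices must be indexed by month (DatetimeIndex)")
    pc_time = pd.PeriodIndex(result.time, freq="M")
    idx_time = pd.PeriodIndex(indices.index, freq="M")
    rows = []
    for m in range(result.k):
        pc = pd.Series(result.pcs[:, m], index=pc_time)
        for name in indices.columns:
            ser = pd.Series(indices[name].values, index=idx_time).dropna()
            joined = pd.concat([pc, ser], axis=1, join="inner").dropna()
            if len(joined) < min_months:
                warnings.warn(
                    f"PC{m + 1} vs {name}: only {len(joined)} common months; skipped",
                    stacklevel=2,
                )
                continue
            r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
            rows.append({"mode": m + 1, "index": name, "r": r, "n": len(joined)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(["mode", "abs_r"], ascending=[True, False]).drop(columns="abs_r")
    df["best"] = ~df.duplicated("mode")
    return df.reset_index(drop=True)


def pc_npp_range(result: EOFResult, mode: int = 0) -> float:
    """Peak-to-peak range of a mode's global-integral NPP anomaly, Pg C yr-1.

    The mode's contribution to the global NPP anomaly at time t is
    sum_cells pattern(cell) * area(cell) * PC(t); converted from
    mg C d-1 to Pg C yr-1.  Requires the field to be in NPP anomaly units.
    """
    if "mg C" not in result.units:
        raise UnitsError(f"pc_npp_range needs NPP units (mg C ...), got {result.units!r}")
    integral_mg_per_day = float((result.modes[mode] * result.cell_area).sum())
    series = integral_mg_per_day * result.pcs[:, mode]
    series_pg_yr = series * MG_TO_PG * DAYS_PER_YEAR
    return float(series_pg_yr.max() - series_pg_yr.min())
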