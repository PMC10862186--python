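"""Distribution-mapping bias correction of coarse climate series.

A coarse climate product (e.g. a reanalysis) and local station
observations rarely share a distribution. The correction fitted here is a
smooth monotone transfer function between the two: both series are
resampled onto equally spaced probability points of their empirical
quantile functions, a penalized cubic spline (smoothing chosen by
generalized cross-validation) regresses the observed quantiles on the
coarse quantiles, and the fitted curve — made monotone by
pooled-adjacent-violators — is tabulated on a dense, equally spaced value
grid spanning the union of both ranges. Applying the map to a longer
coarse record is then a table lookup with linear interpolation, continued
linearly beyond the grid with the boundary slopes.

Precipitation additionally receives a wet-day adjustment: coarse products
drizzle too often, so the coarse days with the smallest positive totals
are zeroed until the coarse dry-day fraction matches the observed one.

An alternative "paired" mode fits the spline on time-matched hourly pairs
instead of quantiles; quantile mode is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

__all__ = ["TransferMap", "WetDayAdjustment", "fit_transfer", "apply_transfer",
           "wet_day_adjust"]

logger = logging.getLogger(__name__)

#: Fraction of the grid span beyond which applied values are counted as
#: far-out-of-range extrapolations.
_EXTRAP_WARN_FRACTION = 0.20

#: Number of evenly spaced abscissa bins the support points are averaged
#: into before the spline fit. Binning conditions the banded spline
#: system (raw quantile pairs carry near-duplicate abscissae) and loses
#: nothing for a smooth transfer function.
_N_SUPPORT_BINS = 1000


@dataclass
class TransferMap:
    """A fitted monotone coarse→observed transfer function.

    ``grid`` holds equally spaced coarse values spanning the union of both
    training ranges; ``fitted_curve`` the corrected value at each grid
    point (monotone non-decreasing). Evaluation interpolates linearly
    within the grid and continues the boundary slopes outside it, so the
    map can be serialized as a two-column table and reloaded bit-exactly.
    """

    variable_name: str
    grid: np.ndarray
    fitted_curve: np.ndarray
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.fitted_curve = np.asarray(self.fitted_curve, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.fitted_curve.shape:
            raise ValueError("grid and fitted_curve must be 1-D and congruent")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.fitted_curve) < -1e-12):
            raise ValueError("fitted_curve must be monotone non-decreasing")

    def __call__(self, values) -> np.ndarray:
        return apply_transfer(self, values)

    def to_csv(self, path) -> None:
        pd.DataFrame({"coarse_value": self.grid,
                      "corrected_value": self.fitted_curve}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, variable_name: str = "") -> "TransferMap":
        table = pd.read_csv(path)
        return cls(variable_name, table["coarse_value"].to_numpy(),
                   table["corrected_value"].to_numpy())


@dataclass(frozen=True)
class WetDayAdjustment:
    """Bookkeeping of one wet-day adjustment."""

    observed_dry_fraction: float
    coarse_dry_fraction: float
    n_days_zeroed: int

    def __post_init__(self) -> None:
        for f in (self.observed_dry_fraction, self.coarse_dry_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("dry fractions must be in [0, 1]")
        if self.n_days_zeroed < 0:
            raise ValueError("n_days_zeroed must be non-negative")


def _clean(series, name: str) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError(f"{name}: series is empty")
    if np.ptp(x) == 0.0:
        raise ValueError(f"{name}: series is constant; no transfer can be fitted")
    return x


def fit_transfer(coarse, observed, n_grid: int = 10_000,
                 variable_name: str = "variable",
                 mode: str = "quantile") -> TransferMap:
    """Fit a smooth monotone coarse→observed transfer function.

    Parameters
    ----------
    coarse, observed
        Training series covering a common period at the same resolution.
    n_grid
        Number of probability points for the quantile pairing and of
        abscissae in the tabulated map.
    mode
        ``"quantile"`` (default) pairs the two empirical quantile
        functions at ``n_grid`` equally spaced probabilities;
        ``"paired"`` uses time-matched (coarse, observed) pairs directly
        and requires equal lengths.
    """
    x_all = _clean(coarse, f"{variable_name} (coarse)")
    y_all = _clean(observed, f"{variable_name} (observed)")
    if min(x_all.size, y_all.size) < 100:
        logger.warning("%s: fewer than 100 training points (%d coarse, %d observed)",
                       variable_name, x_all.size, y_all.size)

    if mode == "quantile":
        p = np.linspace(0.0, 1.0, n_grid)
        x = np.quantile(x_all, p)
        y = np.quantile(y_all, p)
    elif mode == "paired":
        if len(np.asarray(coarse)) != len(np.asarray(observed)):
            raise ValueError("paired mode requires series of equal length")
        order = np.argsort(x_all, kind="stable")
        x, y = x_all[order], y_all[order]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ux, uy = _bin_support(x, y)

    grid_lo = min(x_all.min(), y_all.min())
    grid_hi = max(x_all.max(), y_all.max())
    grid = np.linspace(grid_lo, grid_hi, n_grid)

    if ux.size >= 5:
        spline = _fit_spline(ux, uy)
        fitted = np.asarray(spline(grid), dtype=float)
        resid = uy - np.asarray(spline(ux), dtype=float)
    else:  # too few distinct values for a spline: linear fit
        slope, intercept = np.polyfit(ux, uy, 1)
        fitted = slope * grid + intercept
        resid = uy - (slope * ux + intercept)

    # Outside the support of the training quantiles the spline is an
    # unconstrained polynomial; continue linearly from the support edges.
    fitted = _linearize_tails(grid, fitted, ux.min(), ux.max())

    # Enforce monotonicity by pooled-adjacent-violators on the grid values.
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(grid, fitted)

    diagnostics = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "n_coarse": int(x_all.size),
        "n_observed": int(y_all.size),
        "n_support": int(ux.size),
        "mode": mode,
    }
    return TransferMap(variable_name, grid, fitted, diagnostics)


def _bin_support(x: np.ndarray, y: np.ndarray,
                 n_bins: int = _N_SUPPORT_BINS) -> tuple[np.ndarray, np.ndarray]:
    """Average (x, y) pairs into evenly spaced abscissa bins.

    ``x`` must be sorted. Returns strictly increasing bin-mean abscissae
    with their mean ordinates."""
    edges = np.linspace(x[0], x[-1], n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    bx = np.bincount(idx, weights=x, minlength=n_bins)[occupied] / counts[occupied]
    by = np.bincount(idx, weights=y, minlength=n_bins)[occupied] / counts[occupied]
    keep = np.concatenate([[True], np.diff(bx) > 0])
    return bx[keep], by[keep]


def _fit_spline(ux: np.ndarray, uy: np.ndarray):
    """GCV-penalized cubic smoothing spline, with a small fixed penalty
    as fallback when the GCV search is ill-posed (e.g. effectively
    noise-free ordinates)."""
    try:
        return make_smoothing_spline(ux, uy)
    except (ValueError, np.linalg.LinAlgError):
        span = float(ux[-1] - ux[0])
        last_err: Exception | None = None
        for lam in (1e-8, 1e-6, 1e-4, 1e-2):
            try:
                return make_smoothing_spline(ux, uy, lam=lam * span**3)
            except (ValueError, np.linalg.LinAlgError) as exc:
                last_err = exc
        raise last_err


def _linearize_tails(grid: np.ndarray, fitted: np.ndarray,
                     lo: float, hi: float) -> np.ndarray:
    """Replace the fitted curve outside [lo, hi] with linear continuations
    of the boundary slope just inside the support."""
    out = fitted.copy()
    step = grid[1] - grid[0]
    i_lo = int(np.searchsorted(grid, lo, side="left"))
    i_hi = int(np.searchsorted(grid, hi, side="right")) - 1
    i_lo = min(max(i_lo, 0), grid.size - 2)
    i_hi = min(max(i_hi, 1), grid.size - 1)
    if i_lo > 0:
        slope = (fitted[i_lo + 1] - fitted[i_lo]) / step
        out[:i_lo] = fitted[i_lo] + slope * (grid[:i_lo] - grid[i_lo])
    if i_hi < grid.size - 1:
        slope = (fitted[i_hi] - fitted[i_hi - 1]) / step
        out[i_hi + 1:] = fitted[i_hi] + slope * (grid[i_hi + 1:] - grid[i_hi])
    return out


def apply_transfer(tmap: TransferMap, coarse) -> np.ndarray:
    """Evaluate a fitted map element-wise on a coarse series.

    Linear interpolation on the tabulated grid; beyond the grid the
    boundary slopes continue linearly. Values further than 20% of the grid
    span outside it are corrected anyway but counted and logged.
    """
    x = np.asarray(coarse, dtype=float)
    g, f = tmap.grid, tmap.fitted_curve
    span = g[-1] - g[0]

    out = np.interp(x, g, f)
    slope_lo = (f[1] - f[0]) / (g[1] - g[0])
    slope_hi = (f[-1] - f[-2]) / (g[-1] - g[-2])
    below = x < g[0]
    above = x > g[-1]
    out = np.where(below, f[0] + slope_lo * (x - g[0]), out)
    out = np.where(above, f[-1] + slope_hi * (x - g[-1]), out)

    far = np.sum((x < g[0] - _EXTRAP_WARN_FRACTION * span)
                 | (x > g[-1] + _EXTRAP_WARN_FRACTION * span))
    if far:
        logger.warning("%s: %d values far outside the fitted range were "
                       "linearly extrapolated", tmap.variable_name, int(far))
    return out


def wet_day_adjust(coarse_precip, observed_precip):
    """Match the coarse dry-day fraction to the observed one.

    Both inputs are daily totals (mm). If the coarse series has fewer dry
    days than observed, the coarse days with the smallest positive totals
    are zeroed (earliest first on ties) until the fractions agree to the
    nearest whole day; a coarse series already at least as dry is returned
    unchanged. Returns ``(adjusted, WetDayAdjustment)``.
    """
    coarse = np.asarray(coarse_precip, dtype=float)
    observed = np.asarray(observed_precip, dtype=float)
    if np.any(coarse < 0) or np.any(observed < 0):
        raise ValueError("precipitation must be non-negative")

    obs_dry = float(np.mean(observed == 0.0))
    n = coarse.size
    coarse_dry_n = int(np.sum(coarse == 0.0))
    target_dry_n = int(round(obs_dry * n))

    adjusted = coarse.copy()
    n_zeroed = 0
    if coarse_dry_n < target_dry_n:
        need = target_dry_n - coarse_dry_n
        wet_idx = np.flatnonzero(coarse > 0.0)
        # stable sort: ties on the total zero the earliest days first
        order = wet_idx[np.argsort(coarse[wet_idx], kind="stable")]
        adjusted[order[:need]] = 0.0
        n_zeroed = int(min(need, order.size))

    info = WetDayAdjustment(
        observed_dry_fraction=obs_dry,
        coarse_dry_fraction=float(np.mean(adjusted == 0.0)),
        n_days_zeroed=n_zeroed,
    )
    return adjusted, info
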