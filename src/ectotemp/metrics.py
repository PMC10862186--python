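"""Seasonal thermal-ecology metrics comparing body and air temperature.

Given an hourly body-temperature reconstruction and the matching 2 m air
temperature, compute, per breeding season (May–July, daytime hours):

1. the mean hourly temperature offset (body minus air);
2. body-temperature degree-hours above air temperature, excluding hours
   when the body exceeds the shade-seeking threshold (40 °C) — above it
   the animal would retreat to shade, so those hours carry no activity
   benefit;
3. the number of hours each of body and air temperature exceeds 40 °C;

plus pooled regressions of body on air temperature (linear) and of the
offset on total shortwave radiation (quadratic), and a generic RMSE for
validation against field measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SeasonSummary",
    "RegressionFit",
    "daytime_season_filter",
    "temperature_offset",
    "degree_hours_above_air",
    "hours_above_threshold",
    "fit_linear_tb_tair",
    "fit_quadratic_offset_radiation",
    "summarize_years",
    "rmse",
]

SHADE_SEEKING_THRESHOLD = 40.0  # °C
DAYTIME_HOURS = (6, 19)  # inclusive civil hours
SEASON_MONTHS = (5, 6, 7)  # May–July


@dataclass(frozen=True)
class SeasonSummary:
    """Per-year metrics over the filtered (daytime, May–July) hours."""

    year: int
    mean_offset: float  # °C
    offset_se: float  # °C, standard error of the mean offset
    degree_hours_above_air: float  # °C·h
    hours_Tb_above_40: int
    hours_Tair_above_40: int
    n_hours: int  # hours with complete data entering the metrics


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares fit summary."""

    coefficients: dict
    r_squared: float
    F_statistic: float
    p_value: float
    n: int


def _sorted_by_time(obj):
    if isinstance(obj, (pd.Series, pd.DataFrame)) and isinstance(obj.index, pd.DatetimeIndex):
        return obj.sort_index()
    return obj


def daytime_season_filter(obj, hours: tuple[int, int] = DAYTIME_HOURS,
                          months: tuple[int, ...] = SEASON_MONTHS):
    """Restrict a time-indexed Series/DataFrame to daytime season hours.

    Retains hourly stamps whose civil hour lies in ``hours`` (inclusive on
    both ends; the default 6–19 keeps 14 stamps per day) and whose month
    is in ``months``.
    """
    obj = _sorted_by_time(obj)
    idx = obj.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise TypeError("input must be indexed by timestamps")
    keep = (idx.hour >= hours[0]) & (idx.hour <= hours[1]) & idx.month.isin(months)
    return obj[keep]


def _align(a: pd.Series, b: pd.Series) -> tuple[pd.Series, pd.Series]:
    a, b = _sorted_by_time(a), _sorted_by_time(b)
    if not a.index.equals(b.index):
        raise ValueError("series timestamps are not aligned")
    return a, b


def temperature_offset(t_b: pd.Series, t_air_2m: pd.Series) -> pd.Series:
    """Element-wise body-minus-air temperature offset (°C)."""
    t_b, t_air_2m = _align(t_b, t_air_2m)
    return t_b - t_air_2m


def degree_hours_above_air(t_b: pd.Series, t_air_2m: pd.Series,
                           cap: float = SHADE_SEEKING_THRESHOLD) -> float:
    """Degree-hours of body-temperature excess over air temperature.

    Sum of the positive part of (T_b − T_air) over hours with
    T_b ≤ ``cap``; hours with T_b above the cap contribute nothing (the
    animal would be in shade), and hours with missing data are skipped.
    """
    t_b, t_air_2m = _align(t_b, t_air_2m)
    excess = (t_b - t_air_2m).clip(lower=0.0)
    excess = excess.where(t_b <= cap, 0.0)
    return float(excess.sum(skipna=True))


def hours_above_threshold(series: pd.Series,
                          threshold: float = SHADE_SEEKING_THRESHOLD) -> int:
    """Count hours strictly above a temperature threshold."""
    return int((pd.Series(series) > threshold).sum())


def _ols_fit(y: np.ndarray, X: pd.DataFrame) -> RegressionFit:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionFit(
        coefficients=dict(model.params),
        r_squared=float(model.rsquared),
        F_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(model.nobs),
    )


def fit_linear_tb_tair(t_b, t_air_2m) -> RegressionFit:
    """OLS of body temperature on 2 m air temperature."""
    t_b = np.asarray(t_b, dtype=float)
    t_air = np.asarray(t_air_2m, dtype=float)
    ok = np.isfinite(t_b) & np.isfinite(t_air)
    t_b, t_air = t_b[ok], t_air[ok]
    if t_b.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(t_air) == 0.0:
        raise ValueError("air temperature is constant; slope undefined")
    return _ols_fit(t_b, pd.DataFrame({"T_air": t_air}))


def fit_quadratic_offset_radiation(offset, s_total) -> RegressionFit:
    """OLS of the temperature offset on radiation and radiation squared."""
    off = np.asarray(offset, dtype=float)
    s = np.asarray(s_total, dtype=float)
    ok = np.isfinite(off) & np.isfinite(s)
    off, s = off[ok], s[ok]
    if off.size < 4:
        raise ValueError("need at least 4 paired points")
    if np.ptp(s) == 0.0:
        raise ValueError("radiation is constant; fit undefined")
    return _ols_fit(off, pd.DataFrame({"S": s, "S2": s**2}))


def summarize_years(t_b: pd.Series, t_air_2m: pd.Series, s_total: pd.Series,
                    apply_filter: bool = True):
    """Per-year season summaries plus pooled regressions.

    Returns ``(summaries, fit_tb_tair, fit_offset_radiation)`` where
    ``summaries`` is a DataFrame with one row per calendar year. Inputs
    are hourly, time-indexed and aligned; the daytime/season filter is
    applied unless the caller has filtered already.
    """
    t_b, t_air_2m = _align(t_b, t_air_2m)
    _, s_total = _align(t_b, s_total)
    if apply_filter:
        t_b = daytime_season_filter(t_b)
        t_air_2m = daytime_season_filter(t_air_2m)
        s_total = daytime_season_filter(s_total)

    rows = []
    for year, tb_y in t_b.groupby(t_b.index.year):
        ta_y = t_air_2m.loc[tb_y.index]
        offset = (tb_y - ta_y).dropna()
        n = int(offset.size)
        rows.append(SeasonSummary(
            year=int(year),
            mean_offset=float(offset.mean()) if n else float("nan"),
            offset_se=float(offset.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            degree_hours_above_air=degree_hours_above_air(tb_y, ta_y),
            hours_Tb_above_40=hours_above_threshold(tb_y),
            hours_Tair_above_40=hours_above_threshold(ta_y),
            n_hours=n,
        ))
    summaries = pd.DataFrame([r.__dict__ for r in rows]).set_index("year")

    fit_ta = fit_linear_tb_tair(t_b, t_air_2m)
    fit_rad = fit_quadratic_offset_radiation(t_b - t_air_2m, s_total)
    return summaries, fit_ta, fit_rad


def rmse(predicted, observed) -> float:
    """Root-mean-square error between aligned series (pairs with missing
    values are dropped)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(p) & np.isfinite(o)
    if not ok.any():
        raise ValueError("no overlapping finite values")
    return float(np.sqrt(np.mean((p[ok] - o[ok]) ** 2)))
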