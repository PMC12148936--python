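"""Sap-flow processing: baseline zeroing, daily statistics, flux metrics.

Heat-balance sensors report whole-tree sap flow (kg h^-1) every 15 min.
The raw series sits on a drifting non-zero floor (nighttime offset and slow
sensor drift), removed by fitting the tau = 0.1 quantile regression line of
hourly sap flow against time and subtracting the fitted line.  Corrected
series aggregate to daily 90% quantiles and sums; seasonal regulation is
expressed as the percentage reduction of the daily statistic from the
tree's annual maximum.

Daily quantiles use the linear-interpolation definition (numpy's default),
and the same definition is pinned in the tests' oracle.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: Quantile level of the baseline regression.
BASELINE_TAU = 0.1

#: Minimum hourly points / span for a baseline fit.
MIN_BASELINE_POINTS = 100
MIN_BASELINE_SPAN_DAYS = 7

#: Fraction of slots a day must have to yield valid daily statistics.
COMPLETENESS_THRESHOLD = 0.8


def hourly_mean(series: pd.DataFrame,
                value_col: str = "sap_flow_kg_h") -> pd.DataFrame:
    """Average a 15-min stream to hourly means (columns timestamp, value)."""
    df = series.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = (df.set_index("timestamp")[value_col]
             .resample("1h").mean().dropna().reset_index())
    return out


def quantile_line(x: np.ndarray, y: np.ndarray,
                  tau: float = BASELINE_TAU) -> Tuple[float, float]:
    """Exact tau-quantile regression line of y on x, solved as a linear
    program (HiGHS).

    Minimizes the check loss ``sum(r * (tau - 1[r<0]))`` over intercept and
    slope; the LP solution is an exact vertex optimum, not an iterative
    approximation.  Returns ``(slope, intercept)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(y) == 0:
        return 0.0, float(y[0])
    design = np.column_stack([np.ones(n), x])
    k = design.shape[1]
    cost = np.concatenate([np.zeros(2 * k),
                           tau * np.ones(n), (1 - tau) * np.ones(n)])
    a_eq = sparse.hstack([sparse.csr_matrix(design),
                          -sparse.csr_matrix(design),
                          sparse.eye(n), -sparse.eye(n)], format="csc")
    res = linprog(cost, A_eq=a_eq, b_eq=y,
                  bounds=[(0, None)] * (2 * k + 2 * n), method="highs")
    if res.status != 0:
        raise RuntimeError(f"quantile-regression LP failed: {res.message}")
    beta = res.x[:k] - res.x[k:2 * k]
    return float(beta[1]), float(beta[0])


def fit_baseline(timestamps: pd.Series, values: np.ndarray,
                 tau: float = BASELINE_TAU) -> Tuple[float, float]:
    """Fit the tau-quantile line of value vs time (hours since start).

    Returns ``(slope, intercept)`` in (kg h^-1 per hour, kg h^-1).  A
    degenerate constant series short-circuits to slope 0, intercept = the
    constant.
    """
    t = (pd.to_datetime(timestamps) - pd.to_datetime(timestamps).min())
    hours = t.dt.total_seconds().to_numpy() / 3600.0
    y = np.asarray(values, dtype=float)
    if np.ptp(y) == 0:
        return 0.0, float(y[0])
    return quantile_line(hours, y, tau)


def baseline_correct(series: pd.DataFrame,
                     value_col: str = "sap_flow_kg_h",
                     tau: float = BASELINE_TAU,
                     clip_negative: bool = False) -> Tuple[pd.DataFrame, Tuple[float, float]]:
    """Subtract the tau = 0.1 quantile-regression baseline from hourly sap flow.

    Input must already be hourly (use :func:`hourly_mean` first) with
    columns ``timestamp`` and ``value_col``.  Requires at least 100 points
    spanning at least 7 days.  Returns the corrected frame (column
    ``sap_flow_corrected``) and the fitted ``(slope, intercept)``.

    Corrected values are *not* clipped at zero by default (about 10% of
    hourly values fall below the fitted line by construction); pass
    ``clip_negative=True`` to floor them.
    """
    df = series.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp").reset_index(drop=True)
    y = df[value_col].to_numpy(dtype=float)
    span_days = (df["timestamp"].max() - df["timestamp"].min()).total_seconds() / 86400.0
    if len(df) < MIN_BASELINE_POINTS or span_days < MIN_BASELINE_SPAN_DAYS:
        raise ValueError(
            f"baseline fit needs >= {MIN_BASELINE_POINTS} hourly points over "
            f">= {MIN_BASELINE_SPAN_DAYS} days; got {len(df)} points over "
            f"{span_days:.1f} days")
    slope, intercept = fit_baseline(df["timestamp"], y, tau)
    hours = ((df["timestamp"] - df["timestamp"].min())
             .dt.total_seconds().to_numpy() / 3600.0)
    fitted = intercept + slope * hours
    corrected = y - fitted
    if clip_negative:
        corrected = np.maximum(corrected, 0.0)
    out = df[["timestamp"]].copy()
    out["sap_flow_corrected"] = corrected
    return out, (slope, intercept)


def sf_per_circumference(sf_tree: float, circumference_cm: float,
                         bark_thickness_cm: float) -> float:
    """Sap flow per unit sapwood circumference: ``SF / (A - 2*pi*B)``.

    ``A`` is stem circumference (cm) and ``B`` bark thickness (cm); the
    denominator is the circumference of the cambium, which must be
    positive.
    """
    denom = circumference_cm - 2.0 * math.pi * bark_thickness_cm
    if denom <= 0:
        raise ValueError(
            f"A - 2*pi*B must be > 0 (A={circumference_cm}, B={bark_thickness_cm})")
    return sf_tree / denom


def daily_aggregate(corrected: pd.DataFrame,
                    value_col: str = "sap_flow_corrected",
                    completeness_threshold: float = COMPLETENESS_THRESHOLD,
                    slots_per_day: int = 24) -> pd.DataFrame:
    """Daily 90% quantile and sum of (hourly) corrected sap flow.

    Days with fewer than ``completeness_threshold * slots_per_day`` values
    get NaN statistics and ``valid=False``.  Output columns:
    ``date, q90, daily_sum, completeness, valid``.
    """
    df = corrected.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.floor("D")
    rows = []
    for date, group in df.groupby("date"):
        vals = group[value_col].dropna().to_numpy()
        completeness = len(vals) / slots_per_day
        valid = completeness >= completeness_threshold
        rows.append({
            "date": date,
            "q90": float(np.quantile(vals, 0.9)) if valid else np.nan,
            "daily_sum": float(vals.sum()) if valid else np.nan,
            "daily_max": float(vals.max()) if valid else np.nan,
            "completeness": completeness,
            "valid": valid,
        })
    return pd.DataFrame(rows)


def reduction_from_annual_max(daily: pd.DataFrame,
                              value_col: str = "q90",
                              min_valid_days: int = 30) -> pd.DataFrame:
    """Percent reduction of the daily statistic from the annual maximum.

    ``reduction = 100 * (1 - value / max_year(value))`` per calendar year;
    0% on the annual-maximum day.  Requires at least ``min_valid_days``
    valid days per year.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    out = []
    for year, group in df.groupby("year"):
        vals = group[value_col]
        n_valid = vals.notna().sum()
        if n_valid == 0:
            raise ValueError(f"year {year}: no valid days")
        if n_valid < min_valid_days:
            raise ValueError(
                f"year {year}: only {n_valid} valid days (< {min_valid_days})")
        annual_max = vals.max()
        g = group.copy()
        if annual_max <= 0:
            logger.warning("year %d: non-positive annual max %s; reduction "
                           "undefined", year, annual_max)
            g["reduction_pct"] = np.nan
        else:
            g["reduction_pct"] = 100.0 * (1.0 - vals / annual_max)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def process_tree(raw: pd.DataFrame, circumference_cm: Optional[float] = None,
                 bark_thickness_cm: float = 0.0,
                 value_col: str = "sap_flow_kg_h") -> pd.DataFrame:
    """Raw 15-min series for one tree -> corrected daily statistics.

    Convenience chain: hourly mean -> baseline correction -> daily
    aggregation -> reduction from annual max; optionally divides q90 by the
    sapwood circumference when ``circumference_cm`` is given.
    """
    hourly = hourly_mean(raw, value_col)
    corrected, _ = baseline_correct(hourly, value_col)
    daily = daily_aggregate(corrected)
    daily = reduction_from_annual_max(daily)
    if circumference_cm is not None:
        denom = circumference_cm - 2.0 * math.pi * bark_thickness_cm
        if denom <= 0:
            raise ValueError("A - 2*pi*B must be > 0")
        daily["q90_per_circumference"] = daily["q90"] / denom
    return daily
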