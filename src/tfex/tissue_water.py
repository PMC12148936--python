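"""Leaf and wood water-status metrics.

Three measurement families:

* leaf relative water content, RWC = (M_fresh - M_dry) / (M_turgid - M_dry),
  a 0-1 fraction of full hydration;
* branch volumetric water content, VWC = (M_fresh - M_dry) / V_fresh,
  g of water per cm^3 of fresh sapwood;
* stem VWC from frequency-domain reflectometry, which carries a linear
  temperature artifact removed as
  ``corrected = vwc - (T - T_ref) * b`` with b = -0.000974 per degC (the
  site-calibrated temperature effect) and T_ref the sensor-year mean
  temperature.

Leaf water potentials enter as already-measured MPa values (pressure
chamber); this module only validates and summarizes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Site-calibrated stem-VWC temperature effect (per degC).
DEFAULT_TEMPERATURE_B = -0.000974


@dataclass(frozen=True)
class TissueMasses:
    """Fresh/turgid/dry masses (g) of a leaf or branch-segment sample;
    ``v_fresh`` (cm^3) only for branch segments."""

    m_fresh: float
    m_dry: float
    m_turgid: Optional[float] = None
    v_fresh: Optional[float] = None


def rwc(masses: TissueMasses) -> float:
    """Leaf relative water content (fraction of full hydration).

    ``(M_fresh - M_dry) / (M_turgid - M_dry)``; lies in [0, 1] for valid
    samples.  Samples violating M_dry <= M_fresh <= M_turgid are computed
    anyway but flagged with a warning (field measurement error, not a
    crash).
    """
    if masses.m_turgid is None:
        raise ValueError("rwc requires a turgid mass")
    if masses.m_turgid <= masses.m_dry:
        raise ValueError("M_turgid must exceed M_dry")
    value = (masses.m_fresh - masses.m_dry) / (masses.m_turgid - masses.m_dry)
    if not (0.0 <= value <= 1.0):
        logger.warning("RWC %.3f outside [0,1]: masses fresh=%.4g turgid=%.4g "
                       "dry=%.4g", value, masses.m_fresh, masses.m_turgid,
                       masses.m_dry)
    return value


def branch_vwc(masses: TissueMasses) -> float:
    """Branch volumetric water content (g cm^-3): ``(M_fresh - M_dry)/V_fresh``."""
    if masses.v_fresh is None or masses.v_fresh <= 0:
        raise ValueError("branch_vwc requires V_fresh > 0")
    return (masses.m_fresh - masses.m_dry) / masses.v_fresh


def temperature_correct(vwc_raw, temperature, t_ref: float,
                        b: float = DEFAULT_TEMPERATURE_B):
    """Remove the linear temperature artifact from stem VWC.

    ``corrected = vwc_raw - (temperature - t_ref) * b``, exactly as the
    site calibration prescribes (with the default negative b, readings
    warmer than the reference are adjusted upward).  Accepts scalars or
    arrays.
    """
    v = np.asarray(vwc_raw, dtype=float)
    t = np.asarray(temperature, dtype=float)
    corrected = v - (t - t_ref) * b
    if np.ndim(corrected) == 0:
        return float(corrected)
    return corrected


def correct_stem_series(series: pd.DataFrame,
                        b: float = DEFAULT_TEMPERATURE_B,
                        t_ref: Optional[float] = None) -> pd.DataFrame:
    """Temperature-correct a stem VWC stream (columns
    ``timestamp, vwc_raw, temperature``; optional ``tree_id``).

    ``t_ref`` defaults to the series' mean temperature (per tree when a
    ``tree_id`` column is present), the annual-mean reference point of the
    calibration.  Adds ``vwc_corrected`` and ``t_ref`` columns.
    """
    df = series.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if t_ref is not None:
        df["t_ref"] = t_ref
    elif "tree_id" in df.columns:
        df["t_ref"] = df.groupby("tree_id")["temperature"].transform("mean")
    else:
        df["t_ref"] = df["temperature"].mean()
    df["vwc_corrected"] = df["vwc_raw"] - (df["temperature"] - df["t_ref"]) * b
    return df


def estimate_temperature_slope(series: pd.DataFrame,
                               vwc_col: str = "vwc_raw") -> float:
    """Least-squares slope of stem VWC on (T - mean T).

    Used to *recover* the temperature artifact from data (e.g. to check a
    calibration or validate a correction: after correction the residual
    slope should be ~0).
    """
    t = series["temperature"].to_numpy(dtype=float)
    v = series[vwc_col].to_numpy(dtype=float)
    t_diff = t - t.mean()
    denom = np.sum(t_diff ** 2)
    if denom == 0:
        raise ValueError("temperature has no variance; slope undefined")
    return float(np.sum(t_diff * (v - v.mean())) / denom)


def max_daily_stem_vwc(series: pd.DataFrame,
                       value_col: str = "vwc_corrected") -> pd.DataFrame:
    """Daily maximum stem VWC and its percent reduction from the annual max.

    ``reduction = 100 * (1 - daily_max / annual_max)`` per calendar year.
    Output columns: ``date, daily_max, reduction_pct`` (plus ``tree_id``
    when present).
    """
    df = series.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.floor("D")
    keys = ["tree_id", "date"] if "tree_id" in df.columns else ["date"]
    daily = df.groupby(keys, observed=True)[value_col].max().reset_index()
    daily = daily.rename(columns={value_col: "daily_max"})
    daily["year"] = daily["date"].dt.year
    group_keys = ["tree_id", "year"] if "tree_id" in daily.columns else ["year"]
    annual_max = daily.groupby(group_keys, observed=True)["daily_max"].transform("max")
    daily["reduction_pct"] = 100.0 * (1.0 - daily["daily_max"] / annual_max)
    return daily.drop(columns="year")


def qc_water_potentials(wp: pd.DataFrame) -> pd.DataFrame:
    """Soft QC for leaf water-potential campaigns.

    Flags positive WP values (physically impossible tension) and
    tree-campaign pairs whose mean midday WP exceeds the predawn mean (the
    reverse of the expected diurnal drawdown).  Returns the table with a
    boolean ``qc_flag`` column; nothing is dropped.
    """
    df = wp.copy()
    df["qc_flag"] = df["leaf_wp_mpa"] > 0
    means = (df.groupby(["tree_id", "campaign", "time_of_day"], observed=True)
               ["leaf_wp_mpa"].mean().unstack("time_of_day"))
    if {"predawn", "midday"}.issubset(means.columns):
        suspicious = means[means["midday"] > means["predawn"]].index
        for tree_id, campaign in suspicious:
            logger.warning("WP QC: tree %s campaign %s midday mean above "
                           "predawn mean", tree_id, campaign)
            mask = (df["tree_id"] == tree_id) & (df["campaign"] == campaign)
            df.loc[mask, "qc_flag"] = True
    return df


def average_leaf_replicates(wp: pd.DataFrame,
                            value_col: str = "leaf_wp_mpa") -> pd.DataFrame:
    """Average leaves within branch, then branches within tree.

    Collapses the nested sampling design (>= 2 leaves per branch, up to 3
    branches per tree) to one value per tree-campaign-time_of_day, matching
    the nesting of the downstream mixed models.
    """
    by_branch = (wp.groupby(["tree_id", "campaign", "time_of_day", "branch_id"],
                            observed=True)[value_col].mean().reset_index())
    by_tree = (by_branch.groupby(["tree_id", "campaign", "time_of_day"],
                                 observed=True)[value_col].mean().reset_index())
    return by_tree
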