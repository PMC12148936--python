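"""Soil-moisture profile integration and biomass-relative water availability.

Volumetric water content (VWC, m3 m-3) is monitored at five depths
(0, 0.5, 1, 2.5, 4 m).  The profile integrates to total water (mm) over
0-4 m by the trapezoid rule across the four depth segments; the annual
maximum of the daily-mean total divided by annual plot biomass gives the
biomass-relative water availability statistic (mm per MgC ha^-1), the
stabilization diagnostic of the analysis.

Also houses the meteorological VPD utility (Magnus/Tetens saturation
vapour pressure).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sensor depths (m), fixed by the monitoring design.
SENSOR_DEPTHS = (0.0, 0.5, 1.0, 2.5, 4.0)

#: Magnus/Tetens saturation vapour pressure constants (kPa, dimensionless, degC).
MAGNUS_A = 0.61078
MAGNUS_B = 17.27
MAGNUS_C = 237.3


def _check_depths(depths: Sequence[float]) -> None:
    if tuple(sorted(depths)) != SENSOR_DEPTHS:
        raise ValueError(
            f"expected sensor depths {SENSOR_DEPTHS}, got {tuple(sorted(depths))}")


def integrate_profile(vwc_by_depth: Dict[float, float],
                      strategy: str = "trapezoid",
                      timestamp=None) -> float:
    """Total water (mm) in 0-4 m from one profile of five VWC readings.

    Segments {0-0.5, 0.5-1, 1-2.5, 2.5-4} m each contribute
    ``segment_vwc * thickness_mm``.  With the default ``trapezoid``
    strategy the segment VWC is the mean of the two bounding sensors;
    the ``top`` strategy uses the upper sensor alone (sensitivity option).
    """
    for depth in SENSOR_DEPTHS:
        if depth not in vwc_by_depth or not np.isfinite(vwc_by_depth[depth]):
            raise ValueError(
                f"missing VWC at depth {depth} m"
                + (f" at {timestamp}" if timestamp is not None else ""))
    theta = np.array([vwc_by_depth[d] for d in SENSOR_DEPTHS], dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("VWC values must lie in [0, 1]")
    depths = np.asarray(SENSOR_DEPTHS)
    thickness_mm = np.diff(depths) * 1000.0
    if strategy == "trapezoid":
        seg_vwc = (theta[:-1] + theta[1:]) / 2.0
    elif strategy == "top":
        seg_vwc = theta[:-1]
    else:
        raise ValueError(f"unknown integration strategy {strategy!r}")
    return float(np.sum(seg_vwc * thickness_mm))


def integrate_profile_frame(soil: pd.DataFrame,
                            strategy: str = "trapezoid") -> pd.DataFrame:
    """Vectorized profile integration over a long-format soil table.

    ``soil`` has columns ``plot, timestamp, depth_m, vwc``; returns one row
    per (plot, timestamp) with ``total_water_mm``.
    """
    wide = soil.pivot_table(index=["plot", "timestamp"], columns="depth_m",
                            values="vwc")
    _check_depths(wide.columns.to_list())
    wide = wide[list(SENSOR_DEPTHS)]
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index[0]
        raise ValueError(f"missing VWC reading at {bad}")
    theta = wide.to_numpy()
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("VWC values must lie in [0, 1]")
    thickness_mm = np.diff(np.asarray(SENSOR_DEPTHS)) * 1000.0
    if strategy == "trapezoid":
        seg = (theta[:, :-1] + theta[:, 1:]) / 2.0
    elif strategy == "top":
        seg = theta[:, :-1]
    else:
        raise ValueError(f"unknown integration strategy {strategy!r}")
    total = seg @ thickness_mm
    out = wide.reset_index()[["plot", "timestamp"]]
    out["total_water_mm"] = total
    return out


def annual_max_water(total_water: pd.DataFrame) -> pd.DataFrame:
    """Annual maximum of daily-mean total water, per plot.

    Sub-daily records are first averaged to daily means (the global
    aggregation rule for sensor streams), then the calendar-year maximum is
    taken.  Input columns: ``plot, timestamp, total_water_mm``; output:
    ``plot, year, max_total_water_mm``.
    """
    df = total_water.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.floor("D")
    daily = (df.groupby(["plot", "date"], observed=True)["total_water_mm"]
               .mean().reset_index())
    daily["year"] = daily["date"].dt.year
    out = (daily.groupby(["plot", "year"], observed=True)["total_water_mm"]
                .max().reset_index()
                .rename(columns={"total_water_mm": "max_total_water_mm"}))
    return out


def backfill_pretreatment(annual: pd.DataFrame, first_year: int,
                          control_plot: str = "control") -> pd.DataFrame:
    """Impute pre-monitoring years with the control-plot period mean.

    Soil records often start after the experiment; the missing early years
    (for both plots, pre-treatment conditions being identical) are assigned
    the whole-period control mean, and every imputation is logged.
    """
    control_mean = annual.loc[annual["plot"] == control_plot,
                              "max_total_water_mm"].mean()
    start = int(annual["year"].min())
    rows = []
    for plot in annual["plot"].unique():
        for year in range(first_year, start):
            logger.info("soil backfill: plot=%s year=%d imputed %.1f mm "
                        "(control period mean)", plot, year, control_mean)
            rows.append({"plot": plot, "year": year,
                         "max_total_water_mm": control_mean,
                         "imputed": True})
    if not rows:
        out = annual.copy()
        out["imputed"] = False
        return out
    imputed = pd.DataFrame(rows)
    out = annual.copy()
    out["imputed"] = False
    return (pd.concat([imputed, out], ignore_index=True)
              .sort_values(["plot", "year"]).reset_index(drop=True))


def relative_water_availability(max_water_mm: float, biomass_mgc_ha: float) -> float:
    """Biomass-relative water availability: mm of soil water per MgC ha^-1."""
    if biomass_mgc_ha <= 0:
        raise ValueError("biomass must be > 0")
    return max_water_mm / biomass_mgc_ha


def rwa_series(annual_water: pd.DataFrame, biomass: pd.DataFrame) -> pd.DataFrame:
    """Join annual max water with plot biomass and compute rwa with CI.

    ``biomass`` columns: ``plot, year, agb_lo, agb_mean, agb_hi``.  Division
    by the *higher* biomass bound gives the *lower* rwa bound, so the output
    bounds are re-sorted: ``rwa_lo <= rwa_mean <= rwa_hi``.
    """
    merged = annual_water.merge(biomass, on=["plot", "year"], how="inner")
    out = merged.copy()
    out["rwa_mean"] = merged["max_total_water_mm"] / merged["agb_mean"]
    lo = merged["max_total_water_mm"] / merged["agb_hi"]
    hi = merged["max_total_water_mm"] / merged["agb_lo"]
    out["rwa_lo"] = np.minimum(lo, hi)
    out["rwa_hi"] = np.maximum(lo, hi)
    return out


def vpd_from_t_rh(temperature, relative_humidity):
    """Vapour pressure deficit (kPa) from air temperature (degC) and RH (%).

    Saturation vapour pressure by the Magnus/Tetens formulation
    ``es = 0.61078 * exp(17.27*T / (T + 237.3))``; VPD = es * (1 - RH/100).
    """
    t = np.asarray(temperature, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be in [0, 100]")
    es = MAGNUS_A * np.exp(MAGNUS_B * t / (t + MAGNUS_C))
    vpd = es * (1.0 - rh / 100.0)
    if np.ndim(vpd) == 0:
        return float(vpd)
    return vpd
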