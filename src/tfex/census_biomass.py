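"""Quarterly dendrometer census to annual plot biomass.

The census records circumference *increments* (cm per interval) read off
dendrometer bands four times a year.  Processing steps, in order:

1. per-tree outlier filter: increments more than 3 s.d. from that tree's
   own mean are set to missing (removed, not zero-imputed);
2. annual DBH trajectory: DBH_y = DBH_{y-1} + (annual circumference
   growth)/pi, starting from the initial DBH;
3. plot aggregation: per-tree biomass (mean and 95% CI bounds from wood
   density s.e.) summed over live trees, scaled per hectare, expressed in
   MgC;
4. annual biomass change (ΔBiomass) across consecutive *available* years,
   divided by the year gap (census gap years divide by 2).

Trees leave the biomass sum in their death year; only live aboveground
biomass is tracked.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .allometry import AllometryParams, TreeRecord, agb_with_ci, kg_to_mgc

logger = logging.getLogger(__name__)

#: DBH (cm) separating subcanopy from top-canopy/emergent trees.
CANOPY_DBH_THRESHOLD = 30.0

#: Census inclusion threshold (cm).
CENSUS_MIN_DBH = 10.0


@dataclass
class CensusSeries:
    """Per-tree quarterly circumference-increment series.

    ``observations`` is a DataFrame with columns ``date`` (Timestamp) and
    ``increment_cm`` (circumference increment since the previous reading;
    NaN = missing/removed).  Observations are kept sorted and unique by
    date; none may postdate ``death_date``.
    """

    tree_id: str
    observations: pd.DataFrame
    initial_dbh: float
    death_date: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        obs = self.observations.copy()
        if not {"date", "increment_cm"}.issubset(obs.columns):
            raise ValueError("observations need 'date' and 'increment_cm' columns")
        obs["date"] = pd.to_datetime(obs["date"])
        if obs["date"].duplicated().any():
            raise ValueError(f"tree {self.tree_id}: duplicate observation dates")
        obs = obs.sort_values("date").reset_index(drop=True)
        if self.death_date is not None:
            death = pd.Timestamp(self.death_date)
            if (obs["date"] > death).any():
                raise ValueError(
                    f"tree {self.tree_id}: observations after death date")
        self.observations = obs

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.observations["date"].dt.year.unique())


def filter_growth_outliers(series: CensusSeries) -> Tuple[CensusSeries, pd.DataFrame]:
    """Remove increments more than 3 s.d. from the tree's own mean.

    Mean and s.d. (sample s.d., ddof=1) are computed over the tree's raw
    non-missing increments; values with ``|x - mean| > 3*sd`` (strict) are
    set to NaN.  Returns the filtered series and a removal log with columns
    ``tree_id, date, value``.  Series with fewer than 3 observations pass
    through unchanged with a warning.
    """
    log_cols = ["tree_id", "date", "value"]
    obs = series.observations
    values = obs["increment_cm"]
    n_valid = values.notna().sum()
    if n_valid < 3:
        if n_valid > 0:
            logger.warning(
                "tree %s: only %d increments, outlier filter skipped",
                series.tree_id, n_valid)
        return series, pd.DataFrame(columns=log_cols)
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return series, pd.DataFrame(columns=log_cols)
    mask = (values - mean).abs() > 3.0 * sd
    removed = obs.loc[mask]
    if not mask.any():
        return series, pd.DataFrame(columns=log_cols)
    new_obs = obs.copy()
    new_obs.loc[mask, "increment_cm"] = np.nan
    removal_log = pd.DataFrame({
        "tree_id": series.tree_id,
        "date": removed["date"].values,
        "value": removed["increment_cm"].values,
    })
    for _, row in removal_log.iterrows():
        logger.info("outlier removed: tree %s, %s, %.4f cm",
                    row["tree_id"], row["date"], row["value"])
    filtered = replace(series, observations=new_obs)
    return filtered, removal_log


def dbh_trajectory(series: CensusSeries) -> pd.DataFrame:
    """Annual DBH (cm) from the increment series.

    Returns a DataFrame with columns ``year, dbh, completeness, observed``:
    ``dbh`` is the end-of-year DBH after adding that year's circumference
    growth divided by pi; ``completeness`` is the fraction of the four
    quarters with a non-missing increment; ``observed`` is False for years
    without any reading (the running DBH still carries forward, because the
    next reading's increment accumulates growth across the gap).

    The year before the first observation anchors the trajectory at
    ``initial_dbh``.
    """
    if series.initial_dbh < CENSUS_MIN_DBH:
        logger.warning("tree %s: initial DBH %.2f below census threshold %.0f cm",
                       series.tree_id, series.initial_dbh, CENSUS_MIN_DBH)
    obs = series.observations
    if obs.empty:
        return pd.DataFrame(columns=["year", "dbh", "completeness", "observed"])
    years = np.arange(obs["date"].dt.year.min(), obs["date"].dt.year.max() + 1)
    by_year = obs.set_index(obs["date"].dt.year)["increment_cm"]
    dbh = series.initial_dbh
    rows = []
    for year in years:
        vals = by_year.loc[[year]] if year in by_year.index else pd.Series(dtype=float)
        n_present = int(vals.notna().sum())
        growth = float(vals.sum()) if n_present else 0.0
        dbh = dbh + growth / math.pi
        rows.append({"year": int(year), "dbh": dbh,
                     "completeness": n_present / 4.0,
                     "observed": len(vals) > 0})
    return pd.DataFrame(rows)


def classify_canopy(dbh: float) -> str:
    """``topcanopy_emergent`` if DBH > 30 cm (strict), else ``subcanopy``."""
    if dbh < 0:
        raise ValueError("dbh must be >= 0")
    return "topcanopy_emergent" if dbh > CANOPY_DBH_THRESHOLD else "subcanopy"


def aggregate_plot(trees: Sequence[TreeRecord],
                   trajectories: Dict[str, pd.DataFrame],
                   year: int,
                   params: AllometryParams = AllometryParams(),
                   death_years: Optional[Dict[str, int]] = None,
                   plot_area_ha: float = 1.0) -> dict:
    """One PlotBiomassSeries row: plot biomass totals (MgC ha^-1) for a year.

    Per-tree biomass at the mean wood density and at the 95% CI bounds is
    summed separately over trees alive that year (death year excluded), then
    scaled by plot area.  ``agb_mean_per_tree`` uses the mean instead of the
    sum.  Trees without a DBH entry for the year are skipped.
    """
    death_years = death_years or {}
    lo_sum = mean_sum = hi_sum = 0.0
    n = n_sub = n_top = 0
    for tree in trees:
        dy = death_years.get(tree.tree_id)
        if dy is not None and year >= dy:
            continue
        traj = trajectories.get(tree.tree_id)
        if traj is None:
            raise ValueError(f"tree {tree.tree_id} has no trajectory")
        row = traj.loc[traj["year"] == year]
        if row.empty:
            continue
        dbh = float(row["dbh"].iloc[0])
        lo, mean, hi = agb_with_ci(tree, dbh, params)
        lo_sum += lo
        mean_sum += mean
        hi_sum += hi
        n += 1
        if classify_canopy(dbh) == "subcanopy":
            n_sub += 1
        else:
            n_top += 1
    to_mgc = lambda kg: float(kg_to_mgc(kg, params)) / plot_area_ha
    return {
        "year": int(year),
        "agb_lo": to_mgc(lo_sum),
        "agb_mean": to_mgc(mean_sum),
        "agb_hi": to_mgc(hi_sum),
        "agb_mean_per_tree": float(kg_to_mgc(mean_sum, params)) / n if n else np.nan,
        "n_trees": n,
        "n_subcanopy": n_sub,
        "n_topcanopy": n_top,
    }


def plot_biomass_series(trees: Sequence[TreeRecord],
                        trajectories: Dict[str, pd.DataFrame],
                        params: AllometryParams = AllometryParams(),
                        death_years: Optional[Dict[str, int]] = None,
                        plot_area_ha: float = 1.0) -> pd.DataFrame:
    """Annual PlotBiomassSeries for one plot, with ΔBiomass.

    Years where no tree has an *observed* census reading (gap years) are
    omitted; ΔBiomass then spans the gap, divided by the year difference.
    """
    observed_years: set = set()
    all_years: set = set()
    for traj in trajectories.values():
        if len(traj):
            all_years.update(traj["year"].tolist())
            observed_years.update(traj.loc[traj["observed"], "year"].tolist())
    years = sorted(observed_years)
    rows = [aggregate_plot(trees, trajectories, y, params, death_years,
                           plot_area_ha) for y in years]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["year", "agb_lo", "agb_mean", "agb_hi",
                                     "agb_mean_per_tree", "n_trees",
                                     "n_subcanopy", "n_topcanopy",
                                     "delta_biomass"])
    return delta_biomass(df)


def delta_biomass(series: pd.DataFrame, value_col: str = "agb_mean",
                  out_col: str = "delta_biomass") -> pd.DataFrame:
    """Annual biomass change across consecutive available years.

    ``delta = (AGB_y2 - AGB_y1) / (y2 - y1)`` so a missing census year
    divides the two-year difference by 2.  The first year's delta is NaN.
    """
    df = series.sort_values("year").reset_index(drop=True).copy()
    if len(df) < 2:
        df[out_col] = np.nan
        return df
    dv = df[value_col].diff()
    dy = df["year"].diff()
    df[out_col] = dv / dy
    return df


def percent_biomass_change(initial: float, loss: float) -> float:
    """Biomass loss as a percentage of the initial stock: ``100*loss/initial``."""
    if initial <= 0:
        raise ValueError("initial biomass must be > 0")
    return 100.0 * loss / initial
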