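"""Synthetic two-plot drought-experiment datasets with known ground truth.

Generates everything the downstream pipeline consumes — a two-plot stand
(control and throughfall-exclusion), quarterly dendrometer census series,
multi-year soil-moisture profiles, one year of 15-min sap flow and stem VWC,
and leaf water-potential / tissue-mass campaign tables — from a single seed,
with the planted truth (death years, true growth, true water pools, the
temperature artifact, injected treatment effects) recorded alongside.

The core of the generator is a coupled annual water-balance / demography
loop per plot:

* a daily soil bucket (0-4 m, linear-reservoir drainage) receives rainfall
  (seasonal + stochastic pulses; the TFE plot receives ``1 - exclusion``
  of it) and loses water to drainage and tree uptake;
* daily uptake demand is proportional to live plot biomass; when storage
  hits the residual, uptake is curtailed and the unmet fraction becomes the
  year's water deficit;
* the annual death hazard of each tree is logistic in
  ``deficit * (DBH/30)**mortality_size_bias`` on top of a background rate,
  so drought kills disproportionately large trees;
* growth scales down with deficit, and subcanopy trees gain a
  release-from-competition bonus as plot biomass falls below its initial
  value.

The feedback (mortality -> lower biomass -> lower demand -> deficit
vanishes) is what produces the transition-then-stabilization trajectory the
experiment observed, without scripting it.

Randomness: one root seed; each stream ("demography", "census", "soil",
"hydraulics") derives a child generator from the root seed plus a CRC32
hash of the stream name, so any stream can be regenerated independently and
bit-identically.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .allometry import AllometryParams, TreeRecord, agb_kg, height_from_dbh, kg_to_mgc
from .census_biomass import CensusSeries

logger = logging.getLogger(__name__)

#: Default genus pool: (genus, wood density g cm^-3, s.e.), values in the
#: range reported for eastern Amazonian terra firme genera.
DEFAULT_GENUS_POOL = (
    ("Eschweilera", 0.84, 0.04),
    ("Licania", 0.88, 0.05),
    ("Pouteria", 0.74, 0.05),
    ("Protium", 0.60, 0.04),
    ("Inga", 0.58, 0.05),
    ("Swartzia", 0.90, 0.06),
    ("Virola", 0.48, 0.04),
    ("Tachigali", 0.55, 0.05),
)

SOIL_DEPTH_M = 4.0
SOIL_CAPACITY_MM = 0.45 * SOIL_DEPTH_M * 1000.0   # saturation
SOIL_RESIDUAL_MM = 0.10 * SOIL_DEPTH_M * 1000.0   # unavailable to roots

#: Zero-integral depth patterns (trapezoid integral over 0-4 m is 0), used
#: to add vertical structure to the profile without changing total water.
_PATTERN_SEASON = np.array([1.0, 0.5, 0.0, -0.25, -1.0 / 6.0])
_PATTERN_NOISE = np.array([0.0, 1.0, -0.5, 0.0, 0.0])
SENSOR_DEPTHS = (0.0, 0.5, 1.0, 2.5, 4.0)


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the study conditions: two 1-ha plots of ~500 stems
    (DBH >= 10 cm), ~50% of rainfall excluded on the TFE plot from 2002,
    size-biased drought mortality, quarterly census with gap years, and a
    -0.000974 per-degC temperature artifact on stem VWC.
    """

    n_trees_per_plot: int = 500
    dbh_weibull_shape: float = 0.75
    dbh_weibull_scale: float = 3.5           # cm above the 10 cm threshold
    dbh_min: float = 10.0
    dbh_max: float = 160.0
    genus_pool: Tuple[Tuple[str, float, float], ...] = DEFAULT_GENUS_POOL
    years: Tuple[int, int] = (2002, 2023)
    throughfall_exclusion_fraction: float = 0.5
    mortality_size_bias: float = 1.0
    background_mortality: float = 0.012      # yr^-1, deficit-free hazard
    mortality_deficit_slope: float = 10.0    # logistic slope on deficit*size
    temperature_effect_b: float = -0.000974  # per degC
    seed: int = 0

    # hydrology
    annual_rainfall_mm: float = 2250.0
    wet_season_fraction: float = 0.8         # of rain falling Jan-Jun
    demand_per_mgc: float = 4.4              # mm yr^-1 per MgC ha^-1
    drainage_rate: float = 0.012             # day^-1, linear reservoir
    soil_freq: str = "D"                     # "D" or "h"
    constant_theta: Optional[float] = None   # flat-series diagnostic mode
    soil_noise: float = 1.0                  # scale on pattern-space noise

    # growth / census
    base_growth_cm: float = 0.2              # dbh cm yr^-1 at 30 cm, no stress
    growth_sigma: float = 0.25               # lognormal s.d. of tree-year growth
    census_noise_cm: float = 0.05            # s.d. of quarterly increment noise
    spike_rate: float = 0.01                 # probability of a planted spike
    spike_magnitude_sd: float = 8.0          # spike size in units of series s.d.
    gap_years: Tuple[int, ...] = (2008, 2021)

    # hydraulics monitoring
    n_monitored_per_plot: int = 21
    hydraulics_year: int = 2023
    hydraulics_days: int = 365
    treatment_effect_sd: float = 0.0         # injected TFE shift, in SD units
    stem_vwc_seasonal_amplitude: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.throughfall_exclusion_fraction <= 1.0):
            raise ValueError("throughfall_exclusion_fraction must be in [0, 1]")
        if self.n_trees_per_plot < 0:
            raise ValueError("n_trees_per_plot must be >= 0")
        if self.dbh_min < 10.0:
            raise ValueError("census threshold requires dbh_min >= 10 cm")
        if self.dbh_max <= self.dbh_min:
            raise ValueError("dbh_max must exceed dbh_min")
        for genus, wd, se in self.genus_pool:
            if wd <= 0 or se < 0:
                raise ValueError(f"invalid wood density for genus {genus}")
        if self.years[1] < self.years[0]:
            raise ValueError("years span must be non-empty")
        if self.soil_freq not in ("D", "h"):
            raise ValueError("soil_freq must be 'D' or 'h'")


@dataclass
class GroundTruth:
    """Planted truth of one scenario realization."""

    initial_dbh: Dict[str, float] = field(default_factory=dict)
    death_year: Dict[str, Optional[int]] = field(default_factory=dict)
    true_growth: Optional[pd.DataFrame] = None     # tree_id, year, dbh_increment_cm
    annual_water: Optional[pd.DataFrame] = None    # plot, year, pool, deficit, budget
    daily_storage: Optional[pd.DataFrame] = None   # plot, date, storage_mm
    temperature_b: float = float("nan")
    treatment_effects: Dict[str, float] = field(default_factory=dict)
    planted_spikes: Optional[pd.DataFrame] = None  # tree_id, date, magnitude_cm

    def growth_until_death(self) -> Optional[pd.DataFrame]:
        if self.true_growth is None:
            return None
        def alive(row):
            dy = self.death_year.get(row["tree_id"])
            return dy is None or row["year"] < dy
        return self.true_growth[self.true_growth.apply(alive, axis=1)]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Child generator for a named stream, derived from the root seed."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# Stand generation
# ---------------------------------------------------------------------------

def _truncated_weibull(rng: np.random.Generator, shape: float, scale: float,
                       upper: float, n: int) -> np.ndarray:
    """Weibull draws rejected above ``upper`` (resampled, not clipped)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = scale * rng.weibull(shape, size=max(n - filled, 16))
        draw = draw[draw <= upper]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_stand(config: ScenarioConfig) -> Tuple[List[TreeRecord], GroundTruth]:
    """Two plots with matched genus composition and a shared DBH marginal.

    DBH is ``dbh_min`` plus a truncated Weibull excess; genera are drawn
    from the configured pool with equal probability; bark thickness scales
    weakly with DBH.  Returns the stand and a fresh GroundTruth holding the
    per-tree initial DBH.
    """
    rng = stream_rng(config.seed, "stand")
    trees: List[TreeRecord] = []
    truth = GroundTruth()
    n = config.n_trees_per_plot
    for plot in ("control", "tfe"):
        excess = _truncated_weibull(rng, config.dbh_weibull_shape,
                                    config.dbh_weibull_scale,
                                    config.dbh_max - config.dbh_min, n)
        dbh = config.dbh_min + excess
        genus_idx = rng.integers(0, len(config.genus_pool), size=n)
        for i in range(n):
            genus, wd, se = config.genus_pool[genus_idx[i]]
            tree_id = f"{plot[0].upper()}{i + 1:04d}"
            trees.append(TreeRecord(
                tree_id=tree_id, plot=plot, genus=genus,
                species=f"{genus} sp.",
                wood_density=wd, wood_density_se=se,
                bark_thickness=round(0.3 + 0.01 * dbh[i], 3)))
            truth.initial_dbh[tree_id] = float(dbh[i])
            truth.death_year[tree_id] = None
    truth.temperature_b = config.temperature_effect_b
    return trees, truth


# ---------------------------------------------------------------------------
# Coupled water balance + demography (shared backbone)
# ---------------------------------------------------------------------------

def _daily_rain(rng: np.random.Generator, dates: pd.DatetimeIndex,
                annual_mm: float, wet_fraction: float) -> np.ndarray:
    """Stochastic daily rainfall: seasonal expectation + gamma pulses.

    Wet season (Jan-Jun) carries ``wet_fraction`` of the annual total; rain
    falls on ~45% of wet-season days and ~15% of dry-season days as gamma
    pulses whose means match the seasonal expectation.
    """
    doy = dates.dayofyear.to_numpy()
    wet = doy <= 181
    n_wet, n_dry = 181, 184
    wet_daily = annual_mm * wet_fraction / n_wet
    dry_daily = annual_mm * (1 - wet_fraction) / n_dry
    p_rain = np.where(wet, 0.45, 0.15)
    mean_daily = np.where(wet, wet_daily, dry_daily)
    rains = rng.random(len(dates)) < p_rain
    # gamma shape 0.9: skewed pulses; scale set so E[pulse]*p = mean_daily
    pulse_mean = mean_daily / p_rain
    amounts = rng.gamma(0.9, pulse_mean / 0.9)
    return np.where(rains, amounts, 0.0)


def _plot_agb_mgc(dbh: np.ndarray, wd: np.ndarray, alive: np.ndarray,
                  params: AllometryParams) -> float:
    if not alive.any():
        return 0.0
    d = dbh[alive]
    h = height_from_dbh(d, params)
    kg = agb_kg(d, h, wd[alive], params)
    return float(np.sum(kg_to_mgc(kg, params)))


def _run_demography(stand: Sequence[TreeRecord], truth: GroundTruth,
                    config: ScenarioConfig,
                    params: AllometryParams = AllometryParams()) -> None:
    """Fill truth with death years, true growth and the daily water balance.

    Deterministic given the config seed; both the census and the soil
    simulators call this (idempotently) so their shared backbone is
    bit-identical however the streams are regenerated.
    """
    if truth.annual_water is not None and truth.true_growth is not None:
        return
    rng = stream_rng(config.seed, "demography")
    weather_rng = stream_rng(config.seed, "weather")
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    # one shared weather realization: the plots sit 50 m apart and receive
    # identical rainfall; the TFE panels then exclude a fraction of it
    rain_by_year = {}
    for year in years:
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        rain_by_year[year] = (dates, _daily_rain(
            weather_rng, dates, config.annual_rainfall_mm,
            config.wet_season_fraction))
    growth_rows = []
    water_rows = []
    storage_rows = []

    for plot in ("control", "tfe"):
        plot_trees = [t for t in stand if t.plot == plot]
        ids = np.array([t.tree_id for t in plot_trees])
        wd = np.array([t.wood_density for t in plot_trees])
        dbh = np.array([truth.initial_dbh[t.tree_id] for t in plot_trees])
        alive = np.ones(len(plot_trees), dtype=bool)
        exclusion = (config.throughfall_exclusion_fraction
                     if plot == "tfe" else 0.0)
        agb_init = _plot_agb_mgc(dbh, wd, alive, params)
        storage = 0.55 * SOIL_CAPACITY_MM
        deficit_prev = 0.0

        for year in years:
            agb = _plot_agb_mgc(dbh, wd, alive, params)
            dates, rain_full = rain_by_year[year]
            rain = rain_full * (1.0 - exclusion)
            demand_daily = config.demand_per_mgc * agb / 365.0
            uptake_total = 0.0
            drainage_total = 0.0
            pool_max = storage
            s_start = storage
            day_storage = np.empty(len(dates))
            day_supply = np.empty(len(dates))
            for i in range(len(dates)):
                storage += rain[i]
                drain = config.drainage_rate * max(storage - SOIL_RESIDUAL_MM, 0.0)
                drain = min(drain, max(storage - SOIL_RESIDUAL_MM, 0.0))
                storage -= drain
                drainage_total += drain
                available = max(storage - SOIL_RESIDUAL_MM, 0.0)
                uptake = min(demand_daily, available)
                storage -= uptake
                uptake_total += uptake
                pool_max = max(pool_max, storage)
                day_storage[i] = storage
                day_supply[i] = (uptake / demand_daily
                                 if demand_daily > 0 else 1.0)
            demand_total = demand_daily * len(dates)
            deficit = (1.0 - uptake_total / demand_total) if demand_total > 0 else 0.0
            storage_rows.append(pd.DataFrame(
                {"plot": plot, "date": dates, "storage_mm": day_storage,
                 "rain_mm": rain, "supply_frac": day_supply}))
            water_rows.append({
                "plot": plot, "year": int(year),
                "input_mm": float(rain.sum()),
                "uptake_mm": float(uptake_total),
                "drainage_mm": float(drainage_total),
                "delta_storage_mm": float(storage - s_start),
                "pool_mm": float(pool_max),
                "deficit": float(deficit),
                "agb_true_mgc": float(agb),
            })

            # mortality: logistic hazard in deficit * relative size^bias
            eta0 = logit(config.background_mortality)
            size_term = (dbh / 30.0) ** config.mortality_size_bias
            hazard = expit(eta0 + config.mortality_deficit_slope
                           * deficit_prev * size_term)
            dies = alive & (rng.random(len(dbh)) < hazard)
            for tid in ids[dies]:
                truth.death_year[tid] = int(year)
            alive = alive & ~dies

            # growth of survivors
            release = np.where(
                dbh < 30.0,
                1.0 + 0.5 * np.maximum(0.0, 1.0 - agb / agb_init), 1.0)
            size_factor = np.clip((dbh / 30.0) ** 0.2, 0.5, 2.0)
            stress = max(0.0, 1.0 - 1.5 * deficit_prev)
            growth = (config.base_growth_cm * size_factor * stress * release
                      * np.exp(rng.normal(0.0, config.growth_sigma, len(dbh))))
            growth = np.where(alive, growth, 0.0)
            for j in range(len(ids)):
                if alive[j]:
                    growth_rows.append({"tree_id": ids[j], "year": int(year),
                                        "dbh_increment_cm": float(growth[j])})
            dbh = dbh + growth
            deficit_prev = deficit

    truth.true_growth = pd.DataFrame(growth_rows)
    truth.annual_water = pd.DataFrame(water_rows)
    truth.daily_storage = pd.concat(storage_rows, ignore_index=True)


def ensure_demography(stand: Sequence[TreeRecord], truth: GroundTruth,
                      config: ScenarioConfig) -> GroundTruth:
    """Public wrapper: run (or reuse) the demography backbone."""
    _run_demography(stand, truth, config)
    return truth


# ---------------------------------------------------------------------------
# Census stream
# ---------------------------------------------------------------------------

QUARTER_MONTHS = (1, 4, 7, 10)  # quarters start Jan / Apr / Jul / Oct


def simulate_census(stand: Sequence[TreeRecord], truth: GroundTruth,
                    config: ScenarioConfig) -> pd.DataFrame:
    """Quarterly circumference-increment records for every tree.

    The true annual DBH increment converts to circumference (x pi), splits
    into four quarters with measurement noise, and occasionally carries a
    planted spike (recorded in the truth) to exercise the outlier filter.
    Gap years produce no records; the growth of a gap year accumulates into
    the next observed quarter, as a dendrometer band would.  Dead trees
    stop producing records at their death year.
    """
    if not stand:
        raise ValueError("stand is empty")
    _run_demography(stand, truth, config)
    rng = stream_rng(config.seed, "census")
    growth = truth.true_growth.set_index(["tree_id", "year"])["dbh_increment_cm"]
    by_plot = {t.tree_id: (t.plot, t.genus) for t in stand}
    y0, y1 = config.years
    rows = []
    spikes = []
    for tree in stand:
        tid = tree.tree_id
        death = truth.death_year.get(tid)
        carry = 0.0
        for year in range(y0, y1 + 1):
            if death is not None and year >= death:
                break
            annual_circ = growth.get((tid, year), 0.0) * math.pi
            for month in QUARTER_MONTHS:
                q_increment = annual_circ / 4.0
                if year in config.gap_years:
                    carry += q_increment
                    continue
                value = (q_increment + carry
                         + rng.normal(0.0, config.census_noise_cm))
                carry = 0.0
                date = pd.Timestamp(year=year, month=month, day=1)
                if config.spike_rate > 0 and rng.random() < config.spike_rate:
                    magnitude = (config.spike_magnitude_sd
                                 * config.census_noise_cm
                                 * (1 if rng.random() < 0.5 else -1))
                    value += magnitude
                    spikes.append({"tree_id": tid, "date": date,
                                   "magnitude_cm": magnitude})
                rows.append({"tree_id": tid, "plot": by_plot[tid][0],
                             "genus": by_plot[tid][1], "date": date,
                             "increment_cm": value})
    truth.planted_spikes = pd.DataFrame(
        spikes, columns=["tree_id", "date", "magnitude_cm"])
    return pd.DataFrame(rows, columns=["tree_id", "plot", "genus", "date",
                                       "increment_cm"])


def census_to_series(census: pd.DataFrame, truth: GroundTruth) -> Dict[str, CensusSeries]:
    """Long census table -> per-tree CensusSeries keyed by tree id."""
    out = {}
    for tid, group in census.groupby("tree_id"):
        death = truth.death_year.get(tid)
        death_date = pd.Timestamp(year=death, month=1, day=1) if death else None
        out[tid] = CensusSeries(
            tree_id=tid,
            observations=group[["date", "increment_cm"]]
                .rename(columns={"increment_cm": "increment_cm"}),
            initial_dbh=truth.initial_dbh[tid],
            death_date=death_date)
    return out


# ---------------------------------------------------------------------------
# Soil-moisture stream
# ---------------------------------------------------------------------------

def simulate_soil_moisture(config: ScenarioConfig,
                           stand: Optional[Sequence[TreeRecord]] = None,
                           truth: Optional[GroundTruth] = None) -> pd.DataFrame:
    """Soil VWC at the five sensor depths per plot (long format).

    The profile is the daily bucket storage spread uniformly over 0-4 m
    plus zero-integral depth patterns (seasonal vertical structure and
    sensor noise), so the trapezoid integral of each profile equals the
    bucket storage *exactly* and water is conserved by construction.
    ``constant_theta`` short-circuits to a flat, noise-free series.

    The stand (hence uptake) is regenerated from the config when not
    passed; all streams derive from the root seed, so results are
    identical either way.
    """
    if truth is None or stand is None:
        stand, truth = generate_stand(config)
    _run_demography(stand, truth, config)
    rng = stream_rng(config.seed, "soil")
    frames = []
    for plot in ("control", "tfe"):
        daily = truth.daily_storage[truth.daily_storage["plot"] == plot]
        dates = pd.DatetimeIndex(daily["date"])
        storage = daily["storage_mm"].to_numpy()
        if config.constant_theta is not None:
            theta_base = np.full(len(dates), config.constant_theta)
            season_amp = np.zeros(len(dates))
            noise_amp = np.zeros(len(dates))
        else:
            theta_base = storage / (SOIL_DEPTH_M * 1000.0)
            rain = daily["rain_mm"].to_numpy()
            recent = pd.Series(rain).rolling(10, min_periods=1).mean().to_numpy()
            anomaly = np.clip((recent - recent.mean())
                              / (recent.std() + 1e-12), -1.5, 1.5)
            season_amp = 0.008 * anomaly
            noise_amp = (0.004 * config.soil_noise
                         * np.clip(rng.normal(0, 1, len(dates)), -2, 2))
        if config.soil_freq == "h":
            stamps = pd.DatetimeIndex(
                np.repeat(dates.values, 24)
                + np.tile(pd.to_timedelta(np.arange(24), unit="h"), len(dates)))
            theta_base = np.repeat(theta_base, 24)
            season_amp = np.repeat(season_amp, 24)
            noise_amp = np.repeat(noise_amp, 24)
            if config.constant_theta is None:
                hour = stamps.hour.to_numpy()
                noise_amp = noise_amp + 0.002 * np.sin(2 * np.pi * hour / 24.0)
        else:
            stamps = dates
        profiles = (theta_base[:, None]
                    + season_amp[:, None] * _PATTERN_SEASON[None, :]
                    + noise_amp[:, None] * _PATTERN_NOISE[None, :])
        frame = pd.DataFrame({
            "plot": plot,
            "timestamp": np.repeat(stamps.values, len(SENSOR_DEPTHS)),
            "depth_m": np.tile(SENSOR_DEPTHS, len(stamps)),
            "vwc": profiles.ravel(),
        })
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Hydraulics streams (sap flow, stem VWC, campaigns)
# ---------------------------------------------------------------------------

def _monitored_subset(stand: Sequence[TreeRecord], truth: GroundTruth,
                      config: ScenarioConfig) -> List[TreeRecord]:
    """Size-stratified pick of survivors: small / medium / big per plot."""
    chosen = []
    n = config.n_monitored_per_plot
    n_small = round(n * 8 / 21)
    n_medium = round(n * 8 / 21)
    n_big = n - n_small - n_medium
    for plot in ("control", "tfe"):
        alive = [t for t in stand if t.plot == plot
                 and truth.death_year.get(t.tree_id) is None]
        dbh_now = {t.tree_id: truth.initial_dbh[t.tree_id] for t in alive}
        if truth.true_growth is not None and len(truth.true_growth):
            tot = (truth.true_growth.groupby("tree_id")["dbh_increment_cm"]
                   .sum())
            for t in alive:
                dbh_now[t.tree_id] += float(tot.get(t.tree_id, 0.0))
        small = [t for t in alive if dbh_now[t.tree_id] < 30]
        medium = [t for t in alive if 30 <= dbh_now[t.tree_id] < 60]
        big = [t for t in alive if dbh_now[t.tree_id] >= 60]
        picked: List[TreeRecord] = []
        for pool, k in ((small, n_small), (medium, n_medium), (big, n_big)):
            pool_sorted = sorted(pool, key=lambda t: t.tree_id)
            picked.extend(pool_sorted[:k])
        # top up from whatever is left if a stratum ran short
        if len(picked) < n:
            rest = [t for t in sorted(alive, key=lambda t: t.tree_id)
                    if t not in picked]
            picked.extend(rest[:n - len(picked)])
        chosen.extend(picked[:n])
    return chosen


def simulate_hydraulics(stand: Sequence[TreeRecord],
                        soil: pd.DataFrame,
                        config: ScenarioConfig,
                        truth: GroundTruth) -> Dict[str, pd.DataFrame]:
    """15-min sap flow and stem VWC plus campaign tables for monitored trees.

    Sap flow = per-tree baseline offset (with slow linear drift) + a
    diurnal bell (daylight only) scaled by tree size, plot water
    availability and multiplicative noise — so night readings sit exactly
    on the baseline.  Stem VWC carries a seasonal hydration signal plus the
    additive temperature artifact ``(T - T_mean) * b``.  Leaf water
    potentials track a soil-potential proxy at predawn with a
    transpiration-driven midday drawdown.  A configured treatment effect
    (in SD units) shifts the TFE means of each hydraulic variable and is
    recorded in the truth.

    Returns dict with keys ``sapflow``, ``stem_vwc``, ``leaf_wp``,
    ``tissue``, ``tree_meta``.
    """
    _run_demography(stand, truth, config)
    rng = stream_rng(config.seed, "hydraulics")
    year = config.hydraulics_year
    start = pd.Timestamp(year=year, month=1, day=1)
    n_slots = config.hydraulics_days * 96
    stamps = start + pd.to_timedelta(np.arange(n_slots) * 15, unit="m")
    hour = stamps.hour.to_numpy() + stamps.minute.to_numpy() / 60.0
    doy = stamps.dayofyear.to_numpy()

    # per-tree water availability = demand satisfaction of the plot (uptake
    # over demand, smoothed); after stabilization both plots sit near 1,
    # which is exactly the hydraulic-homeostasis situation
    f_plot = {}
    for plot in ("control", "tfe"):
        daily = truth.daily_storage[
            (truth.daily_storage["plot"] == plot)
            & (truth.daily_storage["date"].dt.year == year)]
        s = daily.set_index(daily["date"].dt.dayofyear)["supply_frac"]
        s_full = s.reindex(np.arange(1, 367)).ffill().bfill()
        frac = s_full.rolling(10, min_periods=1).mean().clip(0.2, 1.0)
        f_plot[plot] = frac.to_numpy()

    bell = np.maximum(0.0, np.sin(np.pi * (hour - 6.0) / 12.0))
    bell[(hour < 6.0) | (hour > 18.0)] = 0.0
    t_season = 25.0 + 1.5 * np.sin(2 * np.pi * (doy - 280) / 365.0)
    temperature = t_season + 4.0 * np.maximum(
        0.0, np.sin(np.pi * (hour - 7.0) / 12.0)) - 1.0

    effect = config.treatment_effect_sd
    truth.treatment_effects = {
        "sap_flow_log": effect * 0.5,    # SD of log daily max across trees
        "leaf_wp_mpa": effect * 0.4,     # SD of midday WP
        "stem_vwc": effect * 0.02,       # SD of stem VWC
    }

    # genus-level random effects (taxonomic signal for the mixed models)
    genus_names = [g for g, _, _ in config.genus_pool]
    genus_sap = dict(zip(genus_names,
                         rng.normal(0.0, 0.15, len(genus_names))))
    genus_wp = dict(zip(genus_names,
                        rng.normal(0.0, 0.08, len(genus_names))))
    genus_vwc = dict(zip(genus_names,
                         rng.normal(0.0, 0.01, len(genus_names))))

    monitored = _monitored_subset(stand, truth, config)
    dbh_final = {}
    tot = truth.true_growth.groupby("tree_id")["dbh_increment_cm"].sum()
    for t in monitored:
        dbh_final[t.tree_id] = truth.initial_dbh[t.tree_id] + float(
            tot.get(t.tree_id, 0.0))

    sap_frames, vwc_frames, wp_rows, tissue_rows, meta_rows = [], [], [], [], []
    campaigns = {"wet_peak": (year, 5, 15), "dry_onset": (year, 7, 15),
                 "dry_peak": (year, 10, 15)}
    for tree in monitored:
        tid = tree.tree_id
        plot = tree.plot
        dbh = dbh_final[tid]
        avail = f_plot[plot][np.minimum(doy - 1, len(f_plot[plot]) - 1)]
        tfe_mult = (math.exp(-truth.treatment_effects["sap_flow_log"])
                    if plot == "tfe" else 1.0)
        amp = (0.004 * dbh ** 2 * math.exp(rng.normal(0.0, 0.3))
               * math.exp(genus_sap.get(tree.genus, 0.0)) * tfe_mult)
        offset = 0.1 + 0.2 * rng.random()
        drift = rng.normal(0.0, 1.5e-5)  # kg h^-1 per hour, sensor drift
        t_hours = np.arange(n_slots) * 0.25
        noise = np.exp(rng.normal(0.0, 0.10, n_slots))
        sap = offset + drift * t_hours + amp * bell * avail * noise
        sap_frames.append(pd.DataFrame({
            "tree_id": tid, "plot": plot, "timestamp": stamps,
            "sap_flow_kg_h": sap}))

        vwc_base = 0.40 + rng.normal(0.0, 0.03) + genus_vwc.get(tree.genus, 0.0)
        if plot == "tfe":
            vwc_base -= truth.treatment_effects["stem_vwc"]
        hydration = config.stem_vwc_seasonal_amplitude * (avail - avail.mean())
        artifact = (temperature - temperature.mean()) * config.temperature_effect_b
        vwc_raw = (vwc_base + hydration + artifact
                   + rng.normal(0.0, 0.001, n_slots))
        vwc_frames.append(pd.DataFrame({
            "tree_id": tid, "plot": plot, "timestamp": stamps,
            "vwc_raw": np.clip(vwc_raw, 0.0, 1.0),
            "temperature": temperature}))

        circumference = math.pi * dbh
        meta_rows.append({"tree_id": tid, "plot": plot, "genus": tree.genus,
                          "dbh_cm": dbh, "circumference_cm": circumference,
                          "bark_thickness_cm": tree.bark_thickness})

        tree_wp_offset = rng.normal(0.0, 0.12) + genus_wp.get(tree.genus, 0.0)
        for campaign, (cy, cm, cd) in campaigns.items():
            date = pd.Timestamp(year=cy, month=cm, day=cd)
            avail_c = f_plot[plot][min(date.dayofyear - 1,
                                       len(f_plot[plot]) - 1)]
            predawn_mean = -0.2 - 1.2 * (1.0 - avail_c) + tree_wp_offset
            midday_mean = predawn_mean - 1.0 - 0.6 * avail_c
            if plot == "tfe":
                predawn_mean -= truth.treatment_effects["leaf_wp_mpa"]
                midday_mean -= truth.treatment_effects["leaf_wp_mpa"]
            for branch in range(1, 4):
                for leaf in range(1, 3):
                    for tod, mu in (("predawn", predawn_mean),
                                    ("midday", midday_mean)):
                        wp_rows.append({
                            "tree_id": tid, "plot": plot, "genus": tree.genus,
                            "dbh_cm": dbh, "campaign": campaign,
                            "time_of_day": tod, "branch_id": branch,
                            "leaf_replicate": leaf,
                            "leaf_wp_mpa": min(-0.01,
                                               mu + rng.normal(0.0, 0.15)),
                        })
            if campaign == "dry_peak":
                rwc_true = np.clip(0.78 + 0.15 * avail_c
                                   + rng.normal(0.0, 0.03), 0.05, 0.99)
                m_dry, m_turgid = 0.40, 1.20
                m_fresh = m_dry + rwc_true * (m_turgid - m_dry)
                v_fresh = 1.5 + rng.normal(0.0, 0.2)
                vwc_branch = np.clip(0.45 + 0.1 * avail_c
                                     + rng.normal(0.0, 0.05), 0.05, 1.0)
                seg_dry = 0.8
                tissue_rows.append({
                    "tree_id": tid, "plot": plot, "campaign": campaign,
                    "sample": "leaf", "m_fresh_g": m_fresh,
                    "m_turgid_g": m_turgid, "m_dry_g": m_dry,
                    "v_fresh_cm3": np.nan})
                tissue_rows.append({
                    "tree_id": tid, "plot": plot, "campaign": campaign,
                    "sample": "branch_segment",
                    "m_fresh_g": seg_dry + vwc_branch * abs(v_fresh),
                    "m_turgid_g": np.nan, "m_dry_g": seg_dry,
                    "v_fresh_cm3": abs(v_fresh)})

    return {
        "sapflow": pd.concat(sap_frames, ignore_index=True),
        "stem_vwc": pd.concat(vwc_frames, ignore_index=True),
        "leaf_wp": pd.DataFrame(wp_rows),
        "tissue": pd.DataFrame(tissue_rows),
        "tree_meta": pd.DataFrame(meta_rows),
    }


# ---------------------------------------------------------------------------
# Scenario bundle + writers
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig,
                      include_hydraulics: bool = True) -> Dict[str, object]:
    """Run every stream of one scenario; returns a dict bundle.

    Keys: ``trees, truth, census, soil`` and (optionally) the hydraulics
    tables.
    """
    stand, truth = generate_stand(config)
    bundle: Dict[str, object] = {"trees": stand, "truth": truth,
                                 "config": config}
    if not stand:
        bundle["census"] = pd.DataFrame(
            columns=["tree_id", "plot", "genus", "date", "increment_cm"])
        bundle["soil"] = simulate_soil_moisture(config, stand, truth) \
            if config.n_trees_per_plot else pd.DataFrame()
        return bundle
    bundle["census"] = simulate_census(stand, truth, config)
    bundle["soil"] = simulate_soil_moisture(config, stand, truth)
    if include_hydraulics:
        bundle.update(simulate_hydraulics(stand, bundle["soil"], config, truth))
    return bundle


def write_scenario(bundle: Dict[str, object], outdir) -> None:
    """Write a scenario bundle as plain CSV files + a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trees: List[TreeRecord] = bundle["trees"]
    truth: GroundTruth = bundle["truth"]
    pd.DataFrame([{
        "tree_id": t.tree_id, "plot": t.plot, "genus": t.genus,
        "species": t.species, "wood_density": t.wood_density,
        "wood_density_se": t.wood_density_se,
        "bark_thickness_cm": t.bark_thickness,
        "initial_dbh_cm": truth.initial_dbh[t.tree_id],
    } for t in trees]).to_csv(outdir / "traits.csv", index=False)
    for key, name in (("census", "census.csv"), ("soil", "soil.csv"),
                      ("sapflow", "sapflow.csv"), ("stem_vwc", "stem_vwc.csv"),
                      ("leaf_wp", "leaf_wp.csv"), ("tissue", "tissue.csv"),
                      ("tree_meta", "tree_meta.csv")):
        if key in bundle and isinstance(bundle[key], pd.DataFrame):
            bundle[key].to_csv(outdir / name, index=False)
    sidecar = {
        "death_year": truth.death_year,
        "temperature_b": truth.temperature_b,
        "treatment_effects": truth.treatment_effects,
        "annual_water": (truth.annual_water.to_dict("records")
                         if truth.annual_water is not None else None),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
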