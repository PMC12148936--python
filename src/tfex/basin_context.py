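"""Basin-wide biome context for plot-level biomass and water availability.

Aligned grids of aboveground biomass (MgC ha^-1), annual precipitation and
evapotranspiration (mm yr^-1), and biome class cover the Amazon basin.  The
module samples coordinates within a biome (uniformly, without replacement,
with an explicit representativeness check on the sampled biomass mean),
derives actual water availability as P - ET, and places a single plot value
against a biome's log-biomass distribution with a one-sample t-test.

Real raster products are an optional ingestion path; grids here are plain
numpy arrays plus a JSON-style georeference dict, and a synthetic grid
generator provides self-contained fixtures with biome-specific biomass
distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

BIOMES = ("moist_forest", "dry_forest", "savanna", "other")

#: |sample mean - population mean| must stay below this multiple of the
#: population SD for a sample to count as representative.
SIMILARITY_TOLERANCE_SD = 0.02
MAX_REDRAWS = 20


@dataclass
class BasinGrid:
    """Aligned 2-D grids sharing shape and georeferencing.

    ``biome`` holds integer codes indexing :data:`BIOMES`.
    """

    agb: np.ndarray
    precipitation: np.ndarray
    evapotranspiration: np.ndarray
    biome: np.ndarray
    georef: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.agb.shape, self.precipitation.shape,
                  self.evapotranspiration.shape, self.biome.shape}
        if len(shapes) != 1:
            raise ValueError(f"grids must share one shape, got {shapes}")
        if self.biome.min() < 0 or self.biome.max() >= len(BIOMES):
            raise ValueError("biome codes out of range")

    def biome_mask(self, biome: str) -> np.ndarray:
        return self.biome == BIOMES.index(biome)


def water_availability(precipitation, evapotranspiration):
    """Actual water availability, P - ET (mm yr^-1; may be negative)."""
    p = np.asarray(precipitation, dtype=float)
    et = np.asarray(evapotranspiration, dtype=float)
    out = p - et
    if np.ndim(out) == 0:
        return float(out)
    return out


def sample_biome(grid: BasinGrid, biome: str, n: int, seed: int) -> pd.DataFrame:
    """Sample ``n`` cells of one biome, uniformly without replacement.

    The sampled biomass mean must land within 2% of the full biome
    population SD of the population mean (the representativeness check);
    non-representative draws are re-drawn with a fresh substream, up to a
    bounded retry count.  Returns a DataFrame of per-point values with
    derived ``water_availability``.
    """
    mask = grid.biome_mask(biome)
    rows, cols = np.nonzero(mask)
    if len(rows) < n:
        raise ValueError(
            f"biome {biome!r} has {len(rows)} cells, fewer than n={n}")
    pop_agb = grid.agb[mask]
    pop_mean = float(pop_agb.mean())
    pop_sd = float(pop_agb.std(ddof=0))
    rng = np.random.default_rng(seed)
    for attempt in range(MAX_REDRAWS):
        idx = rng.choice(len(rows), size=n, replace=False)
        sample_mean = float(grid.agb[rows[idx], cols[idx]].mean())
        if pop_sd == 0 or abs(sample_mean - pop_mean) < SIMILARITY_TOLERANCE_SD * pop_sd:
            break
        logger.info("biome %s sample attempt %d not representative "
                    "(mean off by %.3f SD); redrawing", biome, attempt + 1,
                    abs(sample_mean - pop_mean) / pop_sd)
    else:
        raise RuntimeError(
            f"could not draw a representative sample for biome {biome!r} "
            f"after {MAX_REDRAWS} attempts")
    r, c = rows[idx], cols[idx]
    df = pd.DataFrame({
        "biome": biome,
        "row": r,
        "col": c,
        "agb": grid.agb[r, c],
        "precipitation": grid.precipitation[r, c],
        "evapotranspiration": grid.evapotranspiration[r, c],
    })
    df["water_availability"] = water_availability(
        df["precipitation"].to_numpy(), df["evapotranspiration"].to_numpy())
    return df


def plot_vs_distribution_ttest(log_biomass_sample: np.ndarray,
                               plot_biomass: float) -> Tuple[float, float]:
    """One-sample t-test of a log-biomass sample against one plot's value.

    Orientation: ``t = (mean(log sample) - log(plot)) / (sd / sqrt(n))``,
    i.e. t > 0 when the biome's mean log biomass exceeds the plot's.
    Returns ``(t, p)`` with a two-sided p-value.
    """
    x = np.asarray(log_biomass_sample, dtype=float)
    if len(x) < 2:
        raise ValueError("sample must have at least 2 points")
    if plot_biomass <= 0:
        raise ValueError("plot biomass must be > 0")
    if np.isclose(x.std(ddof=1), 0.0):
        raise ValueError("zero-variance sample; t undefined")
    t, p = sps.ttest_1samp(x, np.log(plot_biomass))
    return float(t), float(p)


def mean_difference(plot_biomass: float, biome_sample: pd.DataFrame) -> float:
    """|biome mean biomass - plot biomass| on the raw (non-log) scale."""
    return float(abs(biome_sample["agb"].mean() - plot_biomass))


#: Printed biome biomass distributions (mean, SD in MgC ha^-1) used by the
#: synthetic grid generator.
BIOME_AGB_STATS = {
    "moist_forest": (266.0, 85.15),
    "dry_forest": (124.96, 106.65),
    "savanna": (49.00, 63.96),
}

BIOME_CLIMATE = {  # (P mean, P sd, ET mean, ET sd), mm yr^-1
    "moist_forest": (2400.0, 300.0, 1300.0, 120.0),
    "dry_forest": (1400.0, 250.0, 1150.0, 120.0),
    "savanna": (1200.0, 250.0, 1100.0, 120.0),
}


def make_synthetic_grid(shape: Tuple[int, int] = (150, 150),
                        seed: int = 0) -> BasinGrid:
    """Build a small synthetic basin grid with biome-specific distributions.

    Biomass per biome is drawn from a truncated normal (floored at 0.1
    MgC ha^-1 so log transforms stay defined) with the documented biome
    means/SDs; precipitation and evapotranspiration get biome-typical
    climates.  Biomes occupy contiguous horizontal bands (moist forest
    50%, dry forest 25%, savanna 15%, other 10%).
    """
    rng = np.random.default_rng(seed)
    nrow, ncol = shape
    biome = np.full(shape, BIOMES.index("other"), dtype=int)
    b1 = int(nrow * 0.50)
    b2 = int(nrow * 0.75)
    b3 = int(nrow * 0.90)
    biome[:b1] = BIOMES.index("moist_forest")
    biome[b1:b2] = BIOMES.index("dry_forest")
    biome[b2:b3] = BIOMES.index("savanna")

    agb = np.full(shape, np.nan)
    precip = np.full(shape, np.nan)
    et = np.full(shape, np.nan)
    for name in ("moist_forest", "dry_forest", "savanna"):
        mask = biome == BIOMES.index(name)
        n = int(mask.sum())
        mu, sd = BIOME_AGB_STATS[name]
        agb[mask] = np.maximum(rng.normal(mu, sd, size=n), 0.1)
        pm, ps, em, es = BIOME_CLIMATE[name]
        precip[mask] = np.maximum(rng.normal(pm, ps, size=n), 100.0)
        et[mask] = np.maximum(rng.normal(em, es, size=n), 50.0)
    other = biome == BIOMES.index("other")
    agb[other] = 1.0
    precip[other] = 1000.0
    et[other] = 900.0
    return BasinGrid(agb=agb, precipitation=precip, evapotranspiration=et,
                     biome=biome,
                     georef={"x0": -80.0, "y0": 6.0, "dx": 0.25, "dy": -0.25})


def contextualize_plots(grid: BasinGrid, plot_biomass: Dict[str, float],
                        n: int = 2000, seed: int = 0) -> pd.DataFrame:
    """t-tests and mean differences of each plot against each biome.

    Returns one row per (plot, biome) with the sample size, t statistic,
    p-value and raw-scale mean difference.
    """
    rows = []
    for i, biome in enumerate(("moist_forest", "dry_forest", "savanna")):
        sample = sample_biome(grid, biome, n, seed + i)
        log_agb = np.log(sample["agb"].to_numpy())
        for plot, agb in plot_biomass.items():
            t, p = plot_vs_distribution_ttest(log_agb, agb)
            rows.append({"plot": plot, "biome": biome, "n": n, "t": t, "p": p,
                         "mean_difference": mean_difference(agb, sample)})
    return pd.DataFrame(rows)
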