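"""Site allometric chain: tree height from DBH, aboveground biomass from
wood density, height and DBH, with wood-density uncertainty propagation.

The height model is a saturating exponential in DBH and the biomass model a
power law in the compound ``WD * H * DBH**2``, both with coefficients fitted
for a terra firme rainforest site in the eastern Amazon.  Biomass comes out
in kg dry mass per tree; a carbon fraction converts to MgC.

Note on the height coefficients: evaluated verbatim, the default parameters
give ~137 m at DBH = 30 cm, far above any real canopy.  The chain is kept
exactly as published for the site (height feeds the biomass power law
without capping) because the biomass fit was made against this same height
model; the parameters are user-overridable and an optional ``height_cap``
exists for sensitivity analysis.  See docs/methods.md.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: 95% two-sided normal quantile used for wood-density confidence bounds.
CI_MULTIPLIER = 1.96

#: Lower floor for wood density (g cm^-3) when WD - 1.96*se is non-positive.
WD_FLOOR = 1e-3


@dataclass(frozen=True)
class AllometryParams:
    """Coefficients of the site allometric chain.

    height = asymptote * (1 - exp(-rate * dbh**exponent))   [m, dbh in cm]
    agb    = coefficient * (WD * height * dbh**2)**exponent [kg]
    """

    height_asymptote: float = 227.35
    height_rate: float = 0.139
    height_exponent: float = 0.5550
    agb_coefficient: float = 0.088
    agb_exponent: float = 0.954
    carbon_fraction: float = 0.5
    height_cap: Optional[float] = None  # m; None = no capping (default)

    def __post_init__(self) -> None:
        for name in ("height_asymptote", "height_rate", "height_exponent",
                     "agb_coefficient", "agb_exponent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.carbon_fraction <= 1.0):
            raise ValueError("carbon_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TreeRecord:
    """Static attributes of a censused stem."""

    tree_id: str
    plot: str  # "control" or "tfe"
    genus: str
    species: str = ""
    wood_density: float = 0.6    # g cm^-3
    wood_density_se: float = 0.0  # g cm^-3
    bark_thickness: float = 0.0   # cm

    def __post_init__(self) -> None:
        if self.wood_density <= 0:
            raise ValueError(f"tree {self.tree_id}: wood_density must be > 0")
        if self.wood_density_se < 0:
            raise ValueError(f"tree {self.tree_id}: wood_density_se must be >= 0")
        if self.bark_thickness < 0:
            raise ValueError(f"tree {self.tree_id}: bark_thickness must be >= 0")


def height_from_dbh(dbh, params: AllometryParams = AllometryParams()):
    """Tree height (m) from DBH (cm).

    Saturating exponential, strictly increasing in DBH and bounded above by
    the asymptote; height(0) = 0.  Accepts scalars or arrays.
    """
    dbh_arr = np.asarray(dbh, dtype=float)
    if np.any(dbh_arr < 0):
        raise ValueError("dbh must be >= 0")
    h = params.height_asymptote * (
        1.0 - np.exp(-params.height_rate * dbh_arr ** params.height_exponent)
    )
    if params.height_cap is not None:
        h = np.minimum(h, params.height_cap)
    return float(h) if np.isscalar(dbh) or np.ndim(dbh) == 0 else h


def agb_kg(dbh, height, wood_density, params: AllometryParams = AllometryParams()):
    """Aboveground biomass (kg dry mass) from DBH (cm), height (m) and
    wood density (g cm^-3): ``coefficient * (WD * H * DBH**2)**exponent``.

    Monotone in each argument and homogeneous of degree ``exponent`` in the
    compound WD*H*DBH^2.
    """
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    wd = np.asarray(wood_density, dtype=float)
    if np.any(d < 0) or np.any(h < 0) or np.any(wd < 0):
        raise ValueError("dbh, height and wood_density must all be >= 0")
    agb = params.agb_coefficient * (wd * h * d ** 2) ** params.agb_exponent
    if np.ndim(agb) == 0:
        return float(agb)
    return agb


def agb_with_ci(tree: TreeRecord, dbh: float,
                params: AllometryParams = AllometryParams()):
    """Biomass (kg) evaluated at WD and at WD +/- 1.96*se.

    Returns ``(lo, mean, hi)`` with lo <= mean <= hi.  If the lower wood
    density bound is non-positive it is floored at a small positive value
    and a warning is logged.
    """
    h = height_from_dbh(dbh, params)
    wd = tree.wood_density
    se = tree.wood_density_se
    wd_lo = wd - CI_MULTIPLIER * se
    wd_hi = wd + CI_MULTIPLIER * se
    if wd_lo <= 0:
        logger.warning(
            "tree %s: WD - 1.96*se = %.4f <= 0; flooring at %g",
            tree.tree_id, wd_lo, WD_FLOOR)
        wd_lo = WD_FLOOR
    lo = agb_kg(dbh, h, wd_lo, params)
    mean = agb_kg(dbh, h, wd, params)
    hi = agb_kg(dbh, h, wd_hi, params)
    return lo, mean, hi


def kg_to_mgc(kg, params: AllometryParams = AllometryParams()):
    """Dry biomass (kg) to carbon mass (Mg C) via the carbon fraction."""
    return np.asarray(kg, dtype=float) * params.carbon_fraction / 1000.0


def mgc_to_kg(mgc, params: AllometryParams = AllometryParams()):
    """Inverse of :func:`kg_to_mgc` (lossless to machine precision)."""
    return np.asarray(mgc, dtype=float) * 1000.0 / params.carbon_fraction
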