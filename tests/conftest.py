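"""Shared fixtures: one full default-scenario pipeline run and the
null/power mixed-model simulation studies, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tfex.pipeline import RunConfig, run_pipeline

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from tfex.synthetic_forest import (ScenarioConfig, generate_stand,
                                   simulate_hydraulics, simulate_soil_moisture)
from tfex.treatment_stats import ComparisonSpec, compare_plots

#: Seed of the canonical end-to-end scenario used across the suite.
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_bundle():
    """Full pipeline run on the default synthetic scenario."""
    return run_pipeline(RunConfig(scenario=ScenarioConfig(seed=DEFAULT_SEED)))


def _small_comparison_pvalue(seed: int, exclusion: float,
                             effect_sd: float) -> float:
    """Plot-effect p-value of the leaf-WP mixed model on a small scenario."""
    cfg = ScenarioConfig(seed=seed, n_trees_per_plot=40, years=(2002, 2003),
                         throughfall_exclusion_fraction=exclusion,
                         treatment_effect_sd=effect_sd,
                         n_monitored_per_plot=10, hydraulics_year=2003,
                         hydraulics_days=4, spike_rate=0.0)
    stand, truth = generate_stand(cfg)
    soil = simulate_soil_moisture(cfg, stand, truth)
    hyd = simulate_hydraulics(stand, soil, cfg, truth)
    wp = hyd["leaf_wp"]
    midday = wp[wp["time_of_day"] == "midday"].rename(
        columns={"dbh_cm": "diameter"})
    return compare_plots(midday,
                         ComparisonSpec(response="leaf_wp_mpa")).plot_pvalue


@pytest.fixture(scope="session")
def null_plot_pvalues():
    """50 plot-effect p-values under a true null (no exclusion, no effect)."""
    return np.array([_small_comparison_pvalue(1000 + s, 0.0, 0.0)
                     for s in range(50)])


@pytest.fixture(scope="session")
def power_plot_pvalues():
    """50 plot-effect p-values with a 2-SD injected treatment effect."""
    return np.array([_small_comparison_pvalue(2000 + s, 0.0, 2.0)
                     for s in range(50)])
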