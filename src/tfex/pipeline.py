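"""End-to-end orchestration: scenario (or loaded data) -> experiment report.

Stage order follows the analysis: census -> biomass -> soil/hydro ->
sensor streams -> treatment statistics -> basin context.  The run emits
per-stage CSVs, a phase summary (transition vs stabilization means of
biomass, ΔBiomass and biomass-relative water availability per plot) and a
machine-readable JSON of headline numbers.

The changepoint between phases is a parameter (default: stabilization
begins in 2017), not re-estimated from the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import basin_context, census_biomass, sapflow, soil_hydro, tissue_water
from .allometry import AllometryParams, TreeRecord
from .census_biomass import (CensusSeries, dbh_trajectory,
                             filter_growth_outliers, plot_biomass_series)
from .synthetic_forest import (GroundTruth, ScenarioConfig, census_to_series,
                               simulate_scenario)
from .treatment_stats import ComparisonSpec, compare_plots

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

DEFAULT_STAGES = ("simulate", "biomass", "hydro", "sapflow", "tissue",
                  "stats", "basin")


@dataclass
class RunConfig:
    """One pipeline run: a scenario OR an input directory, plus knobs."""

    scenario: Optional[ScenarioConfig] = None
    input_dir: Optional[Path] = None
    out_dir: Optional[Path] = None
    changepoint_year: int = 2017
    stages: Dict[str, bool] = field(default_factory=dict)
    basin_n: int = 2000
    basin_seed: int = 0

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of scenario / input_dir must be provided")
        for stage in self.stages:
            if stage not in DEFAULT_STAGES:
                raise ValueError(f"unknown stage {stage!r}")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)


def _require(bundle: dict, key: str, stage: str, needed_by: str):
    if key not in bundle:
        raise RuntimeError(
            f"stage {needed_by!r} needs output of stage {stage!r}, which "
            f"did not run")
    return bundle[key]


def phase_summary(series: pd.DataFrame, changepoint_year: int,
                  value_cols: Sequence[str],
                  group_cols: Sequence[str] = ("plot",)) -> pd.DataFrame:
    """Per-phase means and standard errors of annual series.

    Years before ``changepoint_year`` form the transition phase; from the
    changepoint on, the stabilization phase.  Phases with fewer than two
    years get a missing s.e. and a flag.
    """
    df = series.copy()
    df["phase"] = np.where(df["year"] < changepoint_year,
                           "transition", "stabilization")
    rows = []
    for keys, group in df.groupby([*group_cols, "phase"], observed=True):
        row = dict(zip([*group_cols, "phase"], keys))
        row["n_years"] = group["year"].nunique()
        row["se_defined"] = row["n_years"] >= 2
        if not row["se_defined"]:
            logger.warning("phase %s has < 2 years; s.e. missing", keys)
        for col in value_cols:
            vals = group[col].dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_se"] = (float(vals.std(ddof=1) / np.sqrt(len(vals)))
                                if len(vals) >= 2 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def biomass_stage(trees: Sequence[TreeRecord],
                  series_by_tree: Dict[str, CensusSeries],
                  death_years: Dict[str, Optional[int]],
                  params: AllometryParams = AllometryParams()) -> dict:
    """Outlier filter -> DBH trajectories -> per-plot biomass series.

    Returns dict with ``plot_biomass`` (both plots stacked), ``removals``
    (outlier log) and ``trajectories``.
    """
    removals = []
    trajectories: Dict[str, pd.DataFrame] = {}
    for tid, series in series_by_tree.items():
        filtered, log = filter_growth_outliers(series)
        if len(log):
            removals.append(log)
        trajectories[tid] = dbh_trajectory(filtered)
    removals_df = (pd.concat(removals, ignore_index=True) if removals
                   else pd.DataFrame(columns=["tree_id", "date", "value"]))
    by_plot = []
    death_by_year = {k: v for k, v in death_years.items() if v is not None}
    for plot in ("control", "tfe"):
        plot_trees = [t for t in trees if t.plot == plot]
        plot_traj = {t.tree_id: trajectories[t.tree_id] for t in plot_trees
                     if t.tree_id in trajectories}
        pbs = plot_biomass_series(plot_trees, plot_traj, params,
                                  death_by_year)
        pbs.insert(0, "plot", plot)
        by_plot.append(pbs)
    return {"plot_biomass": pd.concat(by_plot, ignore_index=True),
            "removals": removals_df, "trajectories": trajectories}


def hydro_stage(soil: pd.DataFrame, plot_biomass: pd.DataFrame) -> pd.DataFrame:
    """Profile integration -> annual max of daily means -> rwa with CI."""
    total = soil_hydro.integrate_profile_frame(soil)
    annual = soil_hydro.annual_max_water(total)
    return soil_hydro.rwa_series(annual, plot_biomass)


def annual_growth_by_class(trajectories: Dict[str, pd.DataFrame],
                           trees: Sequence[TreeRecord]) -> pd.DataFrame:
    """Mean annual DBH growth (cm yr^-1) per plot, year and canopy class."""
    plot_of = {t.tree_id: t.plot for t in trees}
    rows = []
    for tid, traj in trajectories.items():
        if len(traj) < 2:
            continue
        t = traj.sort_values("year")
        growth = t["dbh"].diff()
        for year, g, dbh in zip(t["year"].iloc[1:], growth.iloc[1:],
                                t["dbh"].iloc[1:]):
            rows.append({"tree_id": tid, "plot": plot_of.get(tid, "?"),
                         "year": int(year), "growth_cm": float(g),
                         "canopy_class": census_biomass.classify_canopy(dbh)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (df.groupby(["plot", "year", "canopy_class"], observed=True)
              ["growth_cm"].mean().reset_index()
              .rename(columns={"growth_cm": "mean_growth"}))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the report bundle.

    The bundle holds every stage output plus ``report`` (the headline JSON
    dict, schema-versioned, all fields present or explicitly null).
    """
    bundle: dict = {}
    if config.scenario is not None:
        if not config.enabled("simulate"):
            raise RuntimeError("stage 'simulate' disabled but a scenario "
                               "config was given")
        scen = simulate_scenario(config.scenario,
                                 include_hydraulics=config.enabled("sapflow")
                                 or config.enabled("tissue")
                                 or config.enabled("stats"))
        bundle.update(scen)
    else:
        bundle.update(load_scenario(config.input_dir))

    truth: Optional[GroundTruth] = bundle.get("truth")
    trees: List[TreeRecord] = bundle["trees"]

    if config.enabled("biomass"):
        census = _require(bundle, "census", "simulate", "biomass")
        series_by_tree = census_to_series(census, truth)
        death_years = truth.death_year if truth else {}
        bundle.update(biomass_stage(trees, series_by_tree, death_years))

    if config.enabled("hydro"):
        soil = _require(bundle, "soil", "simulate", "hydro")
        plot_biomass = _require(bundle, "plot_biomass", "biomass", "hydro")
        bundle["rwa"] = hydro_stage(soil, plot_biomass)

    if config.enabled("sapflow") and "sapflow" in bundle:
        meta = bundle["tree_meta"].set_index("tree_id")
        daily_frames = []
        for tid, raw in bundle["sapflow"].groupby("tree_id"):
            daily = sapflow.process_tree(
                raw, circumference_cm=float(meta.loc[tid, "circumference_cm"]),
                bark_thickness_cm=float(meta.loc[tid, "bark_thickness_cm"]))
            daily.insert(0, "tree_id", tid)
            daily.insert(1, "plot", meta.loc[tid, "plot"])
            daily_frames.append(daily)
        bundle["sapflow_daily"] = pd.concat(daily_frames, ignore_index=True)

    if config.enabled("tissue") and "stem_vwc" in bundle:
        corrected = tissue_water.correct_stem_series(bundle["stem_vwc"])
        bundle["stem_vwc_corrected"] = corrected
        bundle["stem_vwc_daily"] = tissue_water.max_daily_stem_vwc(corrected)

    if config.enabled("stats"):
        bundle["stats"] = _stats_stage(bundle)

    if config.enabled("basin"):
        plot_biomass = _require(bundle, "plot_biomass", "biomass", "basin")
        final_year = plot_biomass["year"].max()
        plot_vals = (plot_biomass[plot_biomass["year"] == final_year]
                     .set_index("plot")["agb_mean"].to_dict())
        grid = basin_context.make_synthetic_grid(seed=config.basin_seed)
        bundle["basin"] = basin_context.contextualize_plots(
            grid, plot_vals, n=config.basin_n, seed=config.basin_seed)

    bundle["report"] = build_report(bundle, config)
    if config.out_dir is not None:
        write_outputs(bundle, config.out_dir)
    return bundle


def _stats_stage(bundle: dict) -> Dict[str, object]:
    """Plot comparisons of the hydraulic variables, where streams exist."""
    out: Dict[str, object] = {}
    meta = bundle.get("tree_meta")
    if "sapflow_daily" not in bundle or meta is None:
        return out
    meta_idx = meta.set_index("tree_id")

    daily = bundle["sapflow_daily"].dropna(subset=["q90"]).copy()
    daily["diameter"] = meta_idx.loc[daily["tree_id"], "dbh_cm"].to_numpy()
    daily["genus"] = meta_idx.loc[daily["tree_id"], "genus"].to_numpy()
    daily = daily[daily["q90"] > 0]
    out["sap_flow_q90"] = compare_plots(
        daily, ComparisonSpec(response="q90"))
    red = daily[daily["reduction_pct"] > 0].rename(
        columns={"reduction_pct": "sap_reduction"})
    if len(red):
        out["sap_reduction"] = compare_plots(
            red, ComparisonSpec(response="sap_reduction"))

    wp = bundle.get("leaf_wp")
    if wp is not None and len(wp):
        midday = wp[wp["time_of_day"] == "midday"].rename(
            columns={"dbh_cm": "diameter"})
        out["leaf_wp_midday"] = compare_plots(
            midday, ComparisonSpec(response="leaf_wp_mpa"))

    stem = bundle.get("stem_vwc_daily")
    if stem is not None and len(stem):
        s = stem.copy()
        s["diameter"] = meta_idx.loc[s["tree_id"], "dbh_cm"].to_numpy()
        s["genus"] = meta_idx.loc[s["tree_id"], "genus"].to_numpy()
        s["plot"] = meta_idx.loc[s["tree_id"], "plot"].to_numpy()
        s = s[s["daily_max"] > 0]
        out["stem_vwc_daily_max"] = compare_plots(
            s, ComparisonSpec(response="daily_max"))
    return out


def build_report(bundle: dict, config: RunConfig) -> dict:
    """Headline numbers as a stable, schema-versioned JSON-able dict."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "changepoint_year": config.changepoint_year,
                    "plots": {}}
    pb = bundle.get("plot_biomass")
    rwa = bundle.get("rwa")
    if pb is not None:
        merged = pb.copy()
        if rwa is not None:
            merged = merged.merge(
                rwa[["plot", "year", "rwa_mean", "max_total_water_mm"]],
                on=["plot", "year"], how="left")
        else:
            merged["rwa_mean"] = np.nan
        summary = phase_summary(
            merged, config.changepoint_year,
            value_cols=["agb_mean", "delta_biomass", "rwa_mean"])
        bundle["phase_summary"] = summary
        for plot in merged["plot"].unique():
            sub = merged[merged["plot"] == plot].sort_values("year")
            first = sub.iloc[0]
            trans = sub[sub["year"] < config.changepoint_year]
            stab = sub[sub["year"] >= config.changepoint_year]
            loss = (float(first["agb_mean"] - trans["agb_mean"].iloc[-1])
                    if len(trans) else None)
            plot_report = {
                "initial_biomass_mgc_ha": float(first["agb_mean"]),
                "final_biomass_mgc_ha": float(sub["agb_mean"].iloc[-1]),
                "transition_loss_mgc_ha": loss,
                "percent_initial_biomass_lost": (
                    census_biomass.percent_biomass_change(
                        float(first["agb_mean"]), loss)
                    if loss is not None else None),
                "stabilization_mean_biomass_mgc_ha": (
                    float(stab["agb_mean"].mean()) if len(stab) else None),
                "delta_biomass_transition_mean": (
                    float(trans["delta_biomass"].mean())
                    if len(trans) else None),
                "delta_biomass_stabilization_mean": (
                    float(stab["delta_biomass"].mean())
                    if len(stab) else None),
                "rwa_transition_mean": (
                    float(trans["rwa_mean"].mean())
                    if trans["rwa_mean"].notna().any() else None),
                "rwa_stabilization_mean": (
                    float(stab["rwa_mean"].mean())
                    if len(stab) and stab["rwa_mean"].notna().any() else None),
                "rwa_final_year": (
                    float(sub["rwa_mean"].iloc[-1])
                    if sub["rwa_mean"].notna().any() else None),
            }
            report["plots"][str(plot)] = plot_report
    stats = bundle.get("stats") or {}
    report["plot_effect_pvalues"] = {
        name: (None if res.plot_pvalue is None else float(res.plot_pvalue))
        for name, res in stats.items()}
    basin = bundle.get("basin")
    report["basin"] = (basin.to_dict("records") if basin is not None else None)
    return report


def write_outputs(bundle: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, name in (("plot_biomass", "plot_biomass.csv"),
                      ("rwa", "rwa.csv"),
                      ("removals", "outlier_removals.csv"),
                      ("sapflow_daily", "sapflow_daily.csv"),
                      ("stem_vwc_daily", "stem_vwc_daily.csv"),
                      ("phase_summary", "phase_summary.csv"),
                      ("basin", "basin_context.csv")):
        if key in bundle and isinstance(bundle[key], pd.DataFrame):
            bundle[key].to_csv(out / name, index=False)
    (out / "report.json").write_text(
        json.dumps(bundle["report"], indent=1, sort_keys=True))


def load_scenario(input_dir) -> dict:
    """Load a previously written scenario directory back into a bundle."""
    d = Path(input_dir)
    if not d.exists():
        raise FileNotFoundError(f"input directory {d} does not exist")
    traits = pd.read_csv(d / "traits.csv")
    trees = [TreeRecord(tree_id=r.tree_id, plot=r.plot, genus=r.genus,
                        species=r.species, wood_density=r.wood_density,
                        wood_density_se=r.wood_density_se,
                        bark_thickness=r.bark_thickness_cm)
             for r in traits.itertuples()]
    truth = GroundTruth(
        initial_dbh=dict(zip(traits["tree_id"], traits["initial_dbh_cm"])))
    sidecar = d / "ground_truth.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        truth.death_year = {k: v for k, v in meta.get("death_year", {}).items()}
        truth.temperature_b = meta.get("temperature_b", float("nan"))
    else:
        truth.death_year = {t.tree_id: None for t in trees}
    bundle = {"trees": trees, "truth": truth}
    for key, name, parse_dates in (
            ("census", "census.csv", ["date"]),
            ("soil", "soil.csv", ["timestamp"]),
            ("sapflow", "sapflow.csv", ["timestamp"]),
            ("stem_vwc", "stem_vwc.csv", ["timestamp"]),
            ("leaf_wp", "leaf_wp.csv", None),
            ("tissue", "tissue.csv", None),
            ("tree_meta", "tree_meta.csv", None)):
        path = d / name
        if path.exists():
            bundle[key] = pd.read_csv(path, parse_dates=parse_dates)
    if "census" not in bundle:
        raise FileNotFoundError(
            f"stage 'biomass' input missing: {d / 'census.csv'}")
    return bundle
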