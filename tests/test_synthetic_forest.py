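"""Generator properties: determinism, planted truth, water conservation."""

import numpy as np
import pandas as pd
import pytest

from tfex.census_biomass import filter_growth_outliers
from tfex.soil_hydro import integrate_profile_frame
from tfex.synthetic_forest import (GroundTruth, ScenarioConfig,
                                   census_to_series, ensure_demography,
                                   generate_stand, simulate_census,
                                   simulate_hydraulics,
                                   simulate_soil_moisture, simulate_scenario)

SMALL = dict(n_trees_per_plot=60, years=(2002, 2006), n_monitored_per_plot=4,
             hydraulics_year=2006, hydraulics_days=3)


def small_config(seed=11, **over):
    kw = {**SMALL, **over}
    return ScenarioConfig(seed=seed, **kw)


class TestStand:
    def test_identical_seed_identical_stand(self):
        s1, t1 = generate_stand(small_config())
        s2, t2 = generate_stand(small_config())
        assert s1 == s2
        assert t1.initial_dbh == t2.initial_dbh

    def test_empty_stand(self):
        stand, truth = generate_stand(small_config(n_trees_per_plot=0))
        assert stand == []
        assert truth.initial_dbh == {}

    def test_genus_pool_and_dbh_bounds(self):
        pool = (("Inga", 0.58, 0.05), ("Virola", 0.48, 0.04),
                ("Licania", 0.88, 0.05))
        cfg = ScenarioConfig(seed=2, n_trees_per_plot=300, genus_pool=pool)
        stand, truth = generate_stand(cfg)
        genera = {t.genus for t in stand}
        assert genera <= {"Inga", "Virola", "Licania"}
        dbh = np.array(list(truth.initial_dbh.values()))
        assert dbh.min() >= 10.0
        assert dbh.max() <= 160.0
        assert len(stand) == 600

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(throughfall_exclusion_fraction=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(genus_pool=(("X", -0.5, 0.01),))


class TestCensus:
    def test_bit_identical_output_under_seed(self):
        cfg = small_config()
        a = simulate_scenario(cfg, include_hydraulics=False)
        b = simulate_scenario(cfg, include_hydraulics=False)
        assert a["census"].to_csv(index=False) == b["census"].to_csv(index=False)
        assert a["soil"].to_csv(index=False) == b["soil"].to_csv(index=False)

    def test_no_observations_after_death_year(self):
        cfg = small_config(seed=3, years=(2002, 2015),
                           mortality_deficit_slope=14.0)
        stand, truth = generate_stand(cfg)
        census = simulate_census(stand, truth, cfg)
        years = census.groupby("tree_id")["date"].max().dt.year
        for tid, death in truth.death_year.items():
            if death is not None and tid in years.index:
                assert years[tid] < death

    def test_spike_planting_rate(self):
        cfg = small_config(seed=5, n_trees_per_plot=150, years=(2002, 2019),
                           spike_rate=0.02, gap_years=())
        stand, truth = generate_stand(cfg)
        census = simulate_census(stand, truth, cfg)
        n_obs = len(census)
        n_spikes = len(truth.planted_spikes)
        assert n_spikes == pytest.approx(0.02 * n_obs, rel=0.30)

    def test_zero_spike_rate_plants_nothing(self):
        cfg = small_config(spike_rate=0.0)
        stand, truth = generate_stand(cfg)
        simulate_census(stand, truth, cfg)
        assert truth.planted_spikes.empty

    def test_gap_years_absent_from_record(self):
        cfg = ScenarioConfig(seed=7, n_trees_per_plot=30, years=(2006, 2010),
                             gap_years=(2008,))
        stand, truth = generate_stand(cfg)
        census = simulate_census(stand, truth, cfg)
        assert 2008 not in census["date"].dt.year.unique()

    def test_planted_spike_recall_through_filter(self):
        # default 8-sd spikes must be caught by the census 3-sd filter;
        # gap years are disabled so the accumulated post-gap increments do
        # not inflate the per-tree s.d. the spikes are measured against
        cfg = small_config(seed=9, n_trees_per_plot=200, years=(2002, 2021),
                           spike_rate=0.01, gap_years=())
        stand, truth = generate_stand(cfg)
        census = simulate_census(stand, truth, cfg)
        series = census_to_series(census, truth)
        removed = set()
        for tid, s in series.items():
            filtered, log = filter_growth_outliers(s)
            for _, row in log.iterrows():
                removed.add((row["tree_id"], pd.Timestamp(row["date"])))
        planted = set(zip(truth.planted_spikes["tree_id"],
                          pd.to_datetime(truth.planted_spikes["date"])))
        assert planted, "scenario should have planted spikes"
        recall = len(planted & removed) / len(planted)
        assert recall >= 0.95


class TestSoil:
    def test_exclusion_scales_input_exactly(self):
        cfg = small_config(throughfall_exclusion_fraction=0.5)
        stand, truth = generate_stand(cfg)
        ensure_demography(stand, truth, cfg)
        aw = truth.annual_water
        ctrl = aw[aw["plot"] == "control"].set_index("year")["input_mm"]
        tfe = aw[aw["plot"] == "tfe"].set_index("year")["input_mm"]
        # both plots share one weather realization, so the ratio is exact
        assert np.allclose(tfe, 0.5 * ctrl, rtol=1e-12)

    def test_zero_exclusion_inputs_identical(self):
        cfg = small_config(throughfall_exclusion_fraction=0.0)
        stand, truth = generate_stand(cfg)
        ensure_demography(stand, truth, cfg)
        aw = truth.annual_water
        ctrl = aw[aw["plot"] == "control"]["input_mm"].to_numpy()
        tfe = aw[aw["plot"] == "tfe"]["input_mm"].to_numpy()
        assert np.allclose(ctrl, tfe, rtol=1e-12)

    def test_constant_theta_mode_flat(self):
        cfg = small_config(constant_theta=0.3)
        soil = simulate_soil_moisture(cfg)
        assert np.allclose(soil["vwc"], 0.3)

    def test_water_conservation_budget(self):
        cfg = small_config()
        stand, truth = generate_stand(cfg)
        ensure_demography(stand, truth, cfg)
        aw = truth.annual_water
        closure = (aw["input_mm"] - aw["drainage_mm"] - aw["uptake_mm"]
                   - aw["delta_storage_mm"])
        scale = aw["input_mm"].clip(lower=1.0)
        assert (closure.abs() / scale < 1e-6).all()

    def test_profile_integrates_back_to_bucket_storage(self):
        # zero-integral depth patterns leave the trapezoid total untouched
        cfg = small_config()
        stand, truth = generate_stand(cfg)
        soil = simulate_soil_moisture(cfg, stand, truth)
        total = integrate_profile_frame(soil)
        daily = truth.daily_storage
        merged = total.merge(
            daily.rename(columns={"date": "timestamp"}),
            on=["plot", "timestamp"])
        assert len(merged) == len(total)
        assert np.allclose(merged["total_water_mm"], merged["storage_mm"],
                           atol=1e-9)

    def test_hourly_mode_daily_means_match_storage(self):
        cfg = small_config(soil_freq="h", years=(2002, 2002))
        stand, truth = generate_stand(cfg)
        soil = simulate_soil_moisture(cfg, stand, truth)
        total = integrate_profile_frame(soil)
        total["date"] = pd.to_datetime(total["timestamp"]).dt.floor("D")
        daily_mean = (total.groupby(["plot", "date"])["total_water_mm"]
                      .mean().reset_index())
        merged = daily_mean.merge(truth.daily_storage, on=["plot", "date"])
        # diurnal wiggle is pattern-space + a sinusoid averaging ~0 daily
        assert np.allclose(merged["total_water_mm"], merged["storage_mm"],
                           rtol=0.02)


class TestHydraulics:
    def _bundle(self, **over):
        cfg = small_config(**over)
        stand, truth = generate_stand(cfg)
        soil = simulate_soil_moisture(cfg, stand, truth)
        return cfg, truth, simulate_hydraulics(stand, soil, cfg, truth)

    def test_night_sap_flow_is_exact_baseline_line(self):
        cfg, truth, hyd = self._bundle()
        sap = hyd["sapflow"]
        one = sap[sap["tree_id"] == sap["tree_id"].iloc[0]].copy()
        hours = (one["timestamp"] - one["timestamp"].min()).dt.total_seconds() / 3600
        night = one["timestamp"].dt.hour < 6
        y, x = one.loc[night, "sap_flow_kg_h"].to_numpy(), hours[night].to_numpy()
        # all night points lie exactly on the offset + drift line
        coeffs = np.polyfit(x, y, 1)
        residuals = y - np.polyval(coeffs, x)
        assert np.max(np.abs(residuals)) < 1e-9

    def test_temperature_artifact_recoverable(self):
        for b_true in (-0.000974, 0.003):
            cfg, truth, hyd = self._bundle(
                seed=21, temperature_effect_b=b_true,
                stem_vwc_seasonal_amplitude=0.0, hydraulics_days=30)
            from tfex.tissue_water import estimate_temperature_slope
            stem = hyd["stem_vwc"]
            one = stem[stem["tree_id"] == stem["tree_id"].iloc[0]]
            assert estimate_temperature_slope(one) == pytest.approx(
                b_true, rel=0.05)

    def test_injected_treatment_effect_recorded(self):
        cfg, truth, hyd = self._bundle(treatment_effect_sd=2.0)
        assert truth.treatment_effects["leaf_wp_mpa"] == pytest.approx(0.8)

    def test_leaf_wp_all_tensions(self):
        cfg, truth, hyd = self._bundle()
        assert (hyd["leaf_wp"]["leaf_wp_mpa"] <= 0).all()

    def test_tissue_mass_ordering(self):
        cfg, truth, hyd = self._bundle()
        leaf = hyd["tissue"].query("sample == 'leaf'")
        assert (leaf["m_dry_g"] <= leaf["m_fresh_g"]).all()
        assert (leaf["m_fresh_g"] <= leaf["m_turgid_g"]).all()
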