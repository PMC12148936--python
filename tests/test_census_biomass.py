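"""Census processing: outlier filter, DBH trajectories, plot aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfex.allometry import AllometryParams, TreeRecord
from tfex.census_biomass import (CensusSeries, aggregate_plot, classify_canopy,
                                 dbh_trajectory, delta_biomass,
                                 filter_growth_outliers,
                                 percent_biomass_change, plot_biomass_series)


def make_series(values, tree_id="t1", start="2005-01-01", initial_dbh=20.0,
                freq="QS"):
    dates = pd.date_range(start, periods=len(values), freq=freq)
    return CensusSeries(
        tree_id=tree_id,
        observations=pd.DataFrame({"date": dates, "increment_cm": values}),
        initial_dbh=initial_dbh)


def brute_force_filter(values):
    """Independent oracle: mean/sd over raw values, strict 3-sd cut."""
    arr = np.asarray(values, dtype=float)
    mean, sd = arr.mean(), arr.std(ddof=1)
    if sd == 0:
        return np.zeros(len(arr), dtype=bool)
    return np.abs(arr - mean) > 3 * sd


class TestOutlierFilter:
    @pytest.mark.parametrize("values", [
        [1, 1, 1, 1, 50],                 # oracle decides (sd inflated by 50)
        [1.0, 1.1, 0.9, 1.0, 1.05, 30.0],
        [0.5] * 12,
        list(np.linspace(0, 2, 20)) + [40.0],
    ])
    def test_agrees_with_brute_force_oracle(self, values):
        series = make_series(values)
        filtered, log = filter_growth_outliers(series)
        removed_mask = filtered.observations["increment_cm"].isna().to_numpy()
        assert np.array_equal(removed_mask, brute_force_filter(values))
        assert len(log) == removed_mask.sum()

    def test_all_equal_removes_nothing(self):
        filtered, log = filter_growth_outliers(make_series([2.0] * 8))
        assert filtered.observations["increment_cm"].notna().all()
        assert log.empty

    def test_short_series_passes_through(self):
        series = make_series([1.0, 100.0])
        filtered, log = filter_growth_outliers(series)
        assert filtered.observations["increment_cm"].notna().all()
        assert log.empty

    def test_planted_spike_recall_and_false_removal(self):
        # 10,000 N(1, 0.1^2) increments + 10-unit spikes (100 sd): all
        # spikes removed; false removals near the 3-sd normal tail rate
        rng = np.random.default_rng(7)
        n, n_spike = 10_000, 50
        values = rng.normal(1.0, 0.1, n)
        spike_idx = rng.choice(n, n_spike, replace=False)
        values[spike_idx] += 10.0
        # split into trees of 100 obs to mimic per-tree filtering
        removed = np.zeros(n, dtype=bool)
        for i in range(0, n, 100):
            chunk = values[i:i + 100]
            series = make_series(chunk, tree_id=f"t{i}")
            filtered, _ = filter_growth_outliers(series)
            removed[i:i + 100] = filtered.observations["increment_cm"].isna()
        assert removed[spike_idx].mean() >= 0.95
        clean = np.ones(n, dtype=bool)
        clean[spike_idx] = False
        false_rate = removed[clean].mean()
        assert false_rate < 0.01  # P(|Z|>3) ~ 0.0027 plus spike leverage


class TestDbhTrajectory:
    def test_pi_circumference_gives_unit_dbh_growth(self):
        series = make_series([math.pi / 4] * 4, initial_dbh=10.0,
                             start="2005-01-01")
        traj = dbh_trajectory(series)
        assert traj["dbh"].iloc[-1] == pytest.approx(11.0, rel=1e-12)

    def test_zero_growth_constant_dbh(self):
        traj = dbh_trajectory(make_series([0.0] * 8, initial_dbh=15.0))
        assert (traj["dbh"] == 15.0).all()

    def test_quarterly_arithmetic(self):
        # 4 quarters of 0.5 cm circumference each on a 20 cm tree
        traj = dbh_trajectory(make_series([0.5] * 4, initial_dbh=20.0))
        assert traj["dbh"].iloc[-1] == pytest.approx(20.0 + 2.0 / math.pi,
                                                     rel=1e-12)

    def test_missing_quarter_flags_completeness(self):
        values = [0.5, np.nan, 0.5, 0.5]
        traj = dbh_trajectory(make_series(values))
        assert traj["completeness"].iloc[0] == 0.75

    def test_nondecreasing_for_nonnegative_growth(self):
        rng = np.random.default_rng(0)
        traj = dbh_trajectory(make_series(rng.uniform(0, 1, 40)))
        assert (np.diff(traj["dbh"]) >= 0).all()


class TestCanopyClass:
    @pytest.mark.parametrize("dbh,expected", [
        (30.0, "subcanopy"),        # boundary: strictly greater than 30
        (30.1, "topcanopy_emergent"),
        (10.0, "subcanopy"),
        (120.0, "topcanopy_emergent"),
    ])
    def test_threshold(self, dbh, expected):
        assert classify_canopy(dbh) == expected


def _stand(n, seed=0):
    rng = np.random.default_rng(seed)
    trees, trajectories = [], {}
    for i in range(n):
        tid = f"s{i}"
        trees.append(TreeRecord(tree_id=tid, plot="control", genus="Pouteria",
                                wood_density=rng.uniform(0.4, 0.9),
                                wood_density_se=rng.uniform(0, 0.08)))
        trajectories[tid] = pd.DataFrame(
            {"year": [2010], "dbh": [rng.uniform(10, 80)],
             "completeness": [1.0], "observed": [True]})
    return trees, trajectories


class TestAggregation:
    def test_single_tree_total(self):
        trees, traj = _stand(1)
        from tfex.allometry import agb_with_ci, kg_to_mgc
        row = aggregate_plot(trees, traj, 2010)
        lo, mean, hi = agb_with_ci(trees[0], traj["s0"]["dbh"].iloc[0])
        assert row["agb_mean"] == pytest.approx(float(kg_to_mgc(mean)))
        assert row["n_trees"] == 1

    def test_killing_largest_tree_removes_its_biomass(self):
        trees, traj = _stand(10)
        full = aggregate_plot(trees, traj, 2010)
        biggest = max(traj, key=lambda k: traj[k]["dbh"].iloc[0])
        without = aggregate_plot(trees, traj, 2010,
                                 death_years={biggest: 2010})
        victim = next(t for t in trees if t.tree_id == biggest)
        from tfex.allometry import agb_with_ci, kg_to_mgc
        _, mean, _ = agb_with_ci(victim, traj[biggest]["dbh"].iloc[0])
        assert (full["agb_mean"] - without["agb_mean"]
                == pytest.approx(float(kg_to_mgc(mean)), rel=1e-12))

    def test_matches_independent_allometry_oracle(self):
        # brute-force oracle codes the full chain from scratch
        trees, traj = _stand(300, seed=3)
        row = aggregate_plot(trees, traj, 2010)
        p = AllometryParams()
        total = 0.0
        for t in trees:
            d = traj[t.tree_id]["dbh"].iloc[0]
            h = p.height_asymptote * (
                1 - math.exp(-p.height_rate * d ** p.height_exponent))
            kg = p.agb_coefficient * (t.wood_density * h * d * d) ** p.agb_exponent
            total += kg * p.carbon_fraction / 1000.0
        assert row["agb_mean"] == pytest.approx(total, rel=1e-9)

    def test_ci_ordering_preserved(self):
        trees, traj = _stand(50, seed=5)
        row = aggregate_plot(trees, traj, 2010)
        assert row["agb_lo"] <= row["agb_mean"] <= row["agb_hi"]

    def test_permutation_invariance(self):
        trees, traj = _stand(20, seed=9)
        a = aggregate_plot(trees, traj, 2010)
        b = aggregate_plot(list(reversed(trees)), traj, 2010)
        assert a["agb_mean"] == pytest.approx(b["agb_mean"], rel=1e-12)


class TestDeltaBiomass:
    def test_consecutive_years(self):
        df = pd.DataFrame({"year": [2015, 2016], "agb_mean": [170.0, 168.0]})
        out = delta_biomass(df)
        assert out["delta_biomass"].iloc[1] == pytest.approx(-2.0)

    def test_gap_year_divides_by_two(self):
        df = pd.DataFrame({"year": [2020, 2022], "agb_mean": [150.0, 154.0]})
        out = delta_biomass(df)
        assert out["delta_biomass"].iloc[1] == pytest.approx(2.0)

    def test_first_year_missing(self):
        df = pd.DataFrame({"year": [2010, 2011], "agb_mean": [100.0, 101.0]})
        assert np.isnan(delta_biomass(df)["delta_biomass"].iloc[0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(50, 400), min_size=2, max_size=15))
    def test_telescoping_identity(self, values):
        years = sorted(np.random.default_rng(0).choice(
            np.arange(2000, 2040), size=len(values), replace=False))
        df = pd.DataFrame({"year": years, "agb_mean": values})
        out = delta_biomass(df)
        recon = (out["delta_biomass"].iloc[1:]
                 * np.diff(out["year"])).sum()
        assert recon == pytest.approx(values_sorted_last(df) - df["agb_mean"].iloc[0],
                                      abs=1e-9)


def values_sorted_last(df):
    return df.sort_values("year")["agb_mean"].iloc[-1]


class TestPercentChange:
    def test_headline_worked_example(self):
        # 85 MgC lost of an initial 248 MgC stock -> prints as 34%
        assert round(percent_biomass_change(248.0, 85.0)) == 34

    def test_zero_loss(self):
        assert percent_biomass_change(100.0, 0.0) == 0.0

    def test_total_loss(self):
        assert percent_biomass_change(55.0, 55.0) == 100.0

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            percent_biomass_change(0.0, 1.0)
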