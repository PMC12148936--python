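# tfex

Analysis pipeline for **throughfall-exclusion (TFE) forest drought
experiments**: from tree census, soil-moisture and plant-hydraulic sensor
streams to plot biomass trajectories, biomass-relative water availability,
hydraulic treatment comparisons and basin-level context — plus a
synthetic-data generator with known ground truth so every stage is testable
without field data.

It is written for ecosystem ecophysiologists working with paired-plot
drought manipulations in tropical forest: one plot has a fraction of its
rainfall excluded by panels for decades, a nearby control does not, and the
question is whether the droughted forest collapses or reaches a new
eco-hydrological equilibrium in which the surviving trees no longer
experience water stress.

## What it computes

**Biomass.** Quarterly dendrometer circumference increments are filtered
per tree (|x − mean| > 3 s.d. removed), accumulated into annual DBH
trajectories (DBH_y = DBH_{y−1} + growth/π), and converted to aboveground
biomass with the site allometric chain

    H (m)     = 227.35 · (1 − exp(−0.139 · DBH^0.5550))
    AGB (kg)  = 0.088 · (WD · H · DBH²)^0.954

with wood density WD (g cm⁻³) from a genus lookup; the WD standard error
propagates into a 95% CI (WD ± 1.96·se), and totals are summed per plot and
year in MgC ha⁻¹ (carbon fraction 0.5). ΔBiomass is the consecutive-year
difference divided by the year gap.

**Water.** Soil volumetric water content at 0, 0.5, 1, 2.5 and 4 m depth
integrates to total water (mm) over 0–4 m by the trapezoid rule; the annual
maximum of the daily means, divided by plot biomass, is the
**biomass-relative water availability** (rwa, mm MgC⁻¹) — the pipeline's
stabilization diagnostic.

**Hydraulics.** Raw 15-min sap flow is zeroed by subtracting each tree's
τ = 0.1 quantile-regression line against time (solved exactly as a linear
program), then aggregated to daily 90% quantiles, sums and percent
reduction from the annual maximum. Stem water content from FDR sensors is
corrected for its linear temperature artifact
(VWC − T_diff·b, b = −0.000974 °C⁻¹); leaf metrics include relative water
content (M_fresh − M_dry)/(M_turgid − M_dry) and branch volumetric water
content (M_fresh − M_dry)/V_fresh.

**Statistics.** Plot comparisons use linear mixed models on transformed
responses (log by default, √ for reduction percentages, |·| then log for
water potentials) with plot and diameter as fixed effects and individual
nested within genus as random effects; reduced models are fitted alongside
and the convergence of conclusions reported. Basin context places a plot's
biomass against biome-level log-biomass distributions with one-sample
t-tests on seeded, representativeness-checked samples.

## Worked example

The synthetic scenario emulates the study conditions — two 1-ha plots of
~500 stems (DBH ≥ 10 cm), 50% throughfall exclusion from 2002, size-biased
drought mortality — with a coupled water-balance/demography feedback, so
the transition-then-stabilization trajectory *emerges* rather than being
scripted:

```python
from tfex import ScenarioConfig, RunConfig, run_pipeline

scenario = ScenarioConfig(seed=1)          # two 1-ha plots, 500 stems each
result = run_pipeline(RunConfig(scenario=scenario))
plots = result["report"]["plots"]

for plot in ("control", "tfe"):
    r = plots[plot]
    print(f"{plot:8s} initial {r['initial_biomass_mgc_ha']:6.1f} MgC/ha | "
          f"transition loss {r['transition_loss_mgc_ha']:6.1f} "
          f"({r['percent_initial_biomass_lost']:5.1f}%) | "
          f"stabilization mean {r['stabilization_mean_biomass_mgc_ha']:6.1f}")
    print(f"{'':8s} rwa transition {r['rwa_transition_mean']:.2f} -> "
          f"stabilization {r['rwa_stabilization_mean']:.2f} mm MgC^-1")
p = result["stats"]["leaf_wp_midday"].plot_pvalue
print(f"midday leaf water potential, plot effect: P = {p:.2f}")
```

prints (≈3 min on one CPU):

```
control  initial  248.2 MgC/ha | transition loss  -10.8 ( -4.4%) | stabilization mean  268.1
         rwa transition 4.11 -> stabilization 4.04 mm MgC^-1
tfe      initial  255.6 MgC/ha | transition loss   67.5 ( 26.4%) | stabilization mean  184.5
         rwa transition 3.33 -> stabilization 3.75 mm MgC^-1
midday leaf water potential, plot effect: P = 0.27
```

Read: the droughted plot sheds about a quarter of its biomass during the
transition phase (2002–2016) while the control keeps accumulating; water
per unit biomass drops under exclusion, then recovers to control-like
values as mortality reduces demand; and by the monitoring year the midday
leaf water potential no longer differs between plots — hydraulic
homeostasis under a halved water supply.

There is also a CLI:

```bash
tfex simulate --config scenario.yaml --seed 5 --out data/
tfex report   --data data/ --out results/
tfex hydro    --soil soil.csv --biomass plot_biomass.csv --out rwa.csv
tfex basin    --plots plots.csv --n 2000 --seed 7 --out context.csv
```

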