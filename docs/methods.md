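# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of `tfex`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute at run time.

## The analysis chain

### Census to biomass

Dendrometer bands record circumference increments (cm) four times a year
(quarters starting January, April, July, October). Processing:

1. **Outlier filter.** For each tree, increments farther than 3 sample
   standard deviations (ddof = 1) from that tree's own mean are set to
   missing — removed, not zero-imputed, because zero-filling would bias the
   DBH trajectory downward. Every removal is logged with tree, date and
   value. Series with fewer than 3 observations pass through with a
   warning; an all-equal series (s.d. 0) removes nothing (strict
   inequality).
2. **DBH trajectory.** DBH_y = DBH_{y−1} + (annual circumference
   growth)/π. Missing quarters contribute zero growth and lower a
   completeness flag. Years with no readings at all (census gap years)
   yield no biomass point; the dendrometer accumulates, so the first
   reading after a gap carries the gap's growth and the trajectory catches
   up.
3. **Allometry.** Height from DBH by a saturating exponential, biomass by
   a power law in WD·H·DBH² (coefficients in the README). Evaluated
   verbatim, the height model yields ≈137 m at DBH = 30 cm — far above a
   real canopy. It is nevertheless applied exactly as published for the
   site, uncapped, because the biomass power law was fitted against this
   same height model and the two only ever appear composed; the
   coefficients are user-overridable (`AllometryParams`) and a
   `height_cap` option exists for sensitivity analysis. Wood-density
   uncertainty propagates by evaluating biomass at WD ± 1.96·se (normal
   95% multiplier; the lower bound floors at 10⁻³ g cm⁻³ with a logged
   warning). kg dry mass converts to MgC with a configurable carbon
   fraction, default 0.5 (the common convention for tropical wood; the
   published site analyses report MgC without stating the fraction).
4. **Aggregation.** Mean and both CI bounds are summed separately over
   live trees (trees leave the sum in their death year; no standing-dead
   pool), scaled by plot area (default 1 ha, so per-hectare numbers are
   raw sums). ΔBiomass = (AGB_y2 − AGB_y1)/(y2 − y1) over consecutive
   *available* years, so a gap year divides by 2. Canopy classes split at
   DBH > 30 cm (strictly greater; 30.0 cm is subcanopy).

### Soil water and the rwa statistic

Five sensors (0, 0.5, 1, 2.5, 4 m) define four segments (0–0.5, 0.5–1,
1–2.5, 2.5–4 m). The sensor-to-segment mapping is not uniquely determined
by the instrumentation; the default takes each segment's VWC as the mean
of its two bounding sensors (trapezoid rule), with a "top-sensor"
alternative behind a flag for sensitivity. Total water (mm) is
Σ segment_vwc × thickness_mm. Annual maxima are taken over **daily means**
(sub-daily records are first averaged per day, matching the global
aggregation rule for sensor streams), and rwa = annual max water / annual
plot biomass. Because dividing by the *upper* biomass bound gives the
*lower* rwa bound, the rwa CI is re-sorted after division. Where soil
records start after the experiment, pre-monitoring years can be imputed
with the control-plot period mean (`backfill_pretreatment`), each
imputation logged.

VPD uses the Magnus/Tetens saturation pressure
es = 0.61078·exp(17.27·T/(T + 237.3)) kPa, VPD = es·(1 − RH/100).

### Sap flow

The τ = 0.1 quantile regression of hourly sap flow on time (hours since
series start) is solved **exactly as a linear program** (HiGHS), not by an
iterative scheme: the LP vertex optimum makes the fit reproducible to
machine precision and testable against a brute-force enumeration oracle.
Preconditions: ≥ 100 hourly points spanning ≥ 7 days; a constant series
short-circuits (baseline = the constant, corrected ≡ 0). Corrected values
are **not** clipped at zero by default (the procedure subtracts, nothing
more; ~10% of hourly values necessarily fall below the τ = 0.1 line), with
an off-by-default clip option. Daily statistics use the
linear-interpolation quantile definition (numpy default), pinned so the
test oracle and implementation agree by construction. A day needs ≥ 80% of
its slots to count (guards the daily q90 against partial-day bias); a
tree-year needs ≥ 30 valid days before reduction-from-annual-max
(100·(1 − q90/max_year)) is computed. The daily 90% quantile — not the
literal maximum — is the default "maximum daily transpiration" statistic,
with the literal max available alongside.

### Tissue water

RWC = (M_fresh − M_dry)/(M_turgid − M_dry); branch VWC =
(M_fresh − M_dry)/V_fresh. Mass-ordering violations are flagged, not
silently accepted. Stem VWC temperature correction is
corrected = raw − (T − T_ref)·b with b = −0.000974 °C⁻¹ by default and
T_ref the sensor-year mean temperature; the sign convention is exactly as
the calibration prescribes (with negative b, warm readings adjust upward).
Raw-count→VWC sensor calibration is out of scope — inputs are calibrated
VWC, the calibration slot pluggable. Leaf replicates average leaves within
branch, then branches within tree, before any cross-plot summary, matching
the nested random-effects structure.

### Treatment statistics

Transform registry (total over pipeline responses): log by default; √ for
reduction percentages; absolute value then log for (negative) water
potentials. The full model is a linear mixed model on the transformed
response with plot and diameter fixed and individual nested within genus
random (statsmodels MixedLM: genus random intercept + per-individual
variance component). Fixed-effect p-values are Wald tests on the
mixed-model estimates — the backend does not provide Satterthwaite degrees
of freedom, and at the suite's group counts the Wald approximation's
calibration is itself verified by simulation (type-I error and p-value
uniformity tests). Singular or boundary fits (non-finite Wald p-values)
degrade stepwise: drop the individual component, then fall back to OLS on
**per-tree means** — never on raw replicate rows, which would be
pseudo-replicated. The reduced model for the convergence check keeps the
individual random intercept and drops genus and diameter; "conclusions
converge" means identical plot-effect sign and identical significance
verdict at α = 0.05. Month-by-month comparisons run the same spec per
month with no multiplicity correction (a Benjamini–Hochberg option exists,
off by default).

### Basin context

Grids are plain aligned numpy arrays (biomass MgC ha⁻¹, precipitation and
evapotranspiration mm yr⁻¹, biome code) with a JSON georeference; real
raster ingestion is a thin optional adapter, and the bundled generator
builds synthetic grids whose biome biomass distributions use documented
means/SDs (moist forest 266 ± 85.15, dry forest 124.96 ± 106.65, savanna
49.00 ± 63.96 MgC ha⁻¹, truncated at 0.1 so logs stay defined). Sampling
is uniform without replacement within a biome, re-drawn (bounded retries)
until the sample's biomass mean sits within 2% of the population SD of the
population mean — the "similar distribution" check made explicit. The
plot-vs-biome test is a one-sample t-test of the log-transformed biome
sample against log(plot biomass), oriented as
t = (sample mean − log plot)/(sd/√n), so t > 0 when the biome's mean log
biomass exceeds the plot's. Water availability is P − ET, allowed
negative.

## The synthetic scenario generator

The generator is first-class, tested code: it defines the study conditions
every downstream stage is verified against.

**What it emulates.** Two 1-ha plots of `n_trees_per_plot` = 500 stems
(DBH ≥ 10 cm; stem density is not published for the site, so 500 ha⁻¹ is a
documented assumption). DBH is 10 cm plus a truncated Weibull excess
(shape 0.75, scale 3.5 cm, resampled above 160 cm) — a reverse-J size
distribution calibrated so the initial plot stock lands near the
experiment's ≈250 MgC ha⁻¹ *under the verbatim allometry*; because that
allometry's heights are inflated, the calibrated stand carries fewer very
large stems than a real hectare. Genera draw uniformly from an
eight-genus pool with terra-firme-typical wood densities (0.48–0.90
g cm⁻³, s.e. 0.04–0.06).

**Coupled water balance and demography.** One shared daily weather
realization (the plots sit ~50 m apart): seasonal rainfall of 2250 mm yr⁻¹
expectation, 80% falling January–June, as gamma-distributed pulses. The
TFE plot receives (1 − exclusion) of it, default 0.5. Each plot runs a
daily 0–4 m bucket (capacity 0.45·4000 mm, residual 0.10·4000 mm,
linear-reservoir drainage 0.012 day⁻¹). Daily uptake demand is
4.4 mm yr⁻¹ per MgC ha⁻¹ of live biomass (an evapotranspiration-like
≈1100 mm yr⁻¹ at 250 MgC ha⁻¹); when storage hits the residual, uptake is
curtailed and the unmet fraction is the year's deficit. Mortality hazard
is logistic: expit(logit(0.012) + 10·deficit·(DBH/30)^bias), bias
default 1 — drought kills disproportionately large trees, the background
rate is ~1.2% yr⁻¹. Growth is 0.2 cm yr⁻¹ at 30 cm DBH, scaled by a weak
size factor, reduced by deficit, amplified (≤ +50%) for subcanopy trees as
plot biomass falls below its initial value (release from competition), and
jittered lognormally per tree-year. The defining feedback — mortality →
lower biomass → lower demand → deficit vanishes → mortality stops — is
what produces transition-then-stabilization; it is not scripted.

Soil profiles spread the bucket storage uniformly over 0–4 m and add
**zero-integral depth patterns** (vertical structure and sensor noise whose
trapezoid integral is exactly zero), so profile integration recovers the
bucket storage to machine precision and the water budget closes
identically (input − drainage − uptake = Δstorage). The soil stream is
daily by default — the analysis aggregates to daily means anyway — with an
hourly mode for tests of the aggregation rule.

Sap flow is a per-tree baseline offset with a slow linear drift plus a
daylight-only diurnal bell scaled by tree size (∝ DBH²), the plot's demand
satisfaction, and multiplicative noise — so night readings sit exactly on
the baseline line. Stem VWC carries a hydration signal, the additive
(T − T̄)·b artifact, and per-tree/genus offsets; leaf water potentials
track a supply proxy at predawn with a transpiration drawdown at midday,
with genus and tree random offsets so the nested mixed models have genuine
variance components. An injected treatment effect (`treatment_effect_sd`,
default 0 — the stabilized experiment's condition) shifts the TFE means of
each hydraulic variable by a known amount recorded in the ground truth.
For temperature-coefficient recovery experiments the hydration signal can
be switched off (`stem_vwc_seasonal_amplitude = 0`), giving a controlled
series where the artifact slope is identifiable by regression.

**Randomness.** One root seed; each stream (stand, demography, weather,
census, soil, hydraulics) derives a child generator from the root seed
plus a CRC32 hash of the stream name, so any stream regenerates
independently and bit-identically.

**What it does not emulate.** No mechanistic soil physics (no Richards
equation, no retention curves), no species-level traits, no atmospheric
drought coupling (VPD forcing is a fixed diurnal shape), no recruitment
into the 10-cm class, no spatial structure within plots, no sensor
failures beyond planted spikes and gap years. Passing tests therefore show
the *pipeline* is correct and that the stabilization signature follows
from the stated feedback — not that a real field dataset would yield
identical numbers.

## Problem sizes and runtimes

The canonical scenario (500 stems/plot, 2002–2023, 21 monitored trees per
plot for one 15-min year) runs the full pipeline in ~3 minutes on one CPU;
the suite's simulation studies use reduced scenarios (40 trees, 2 years,
10 monitored trees, 4 sensor days, 50 seeds) chosen so a calibration
experiment completes in seconds while keeping ≥ 20 trees per comparison.
The basin fixture is a 150×150 grid sampled at n = 2000 per biome.

## Known limitations

* The height allometry discrepancy noted above: absolute biomass values
  are internally consistent but tied to the published, physically
  implausible height curve.
* Wald p-values from MixedLM are mildly anti-conservative at small group
  counts; the simulation checks bound the type-I error at the suite's
  sizes but other designs should re-verify.
* The changepoint year (default 2017) is a parameter, not estimated;
  changepoint detection is out of scope.
* One scenario realization is one experiment: plot-level quantities carry
  the full stochasticity of a single hectare, exactly as the real
  unreplicated manipulation does.
* Real-raster basin ingestion (GeoTIFF reprojection etc.) is a stub by
  design; published basin t-statistics depend on external data products
  and are not reproduced here.
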