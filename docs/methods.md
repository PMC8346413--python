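# Methods

## Model structure

The body is represented as six cylinders — head, torso, arms, legs, hands,
feet — each divided into four concentric compartments (core, muscle, fat,
skin), plus a central blood pool: 25 temperature nodes.  Within a segment,
adjacent compartments exchange heat by radial conduction (constant
conductances K, W/°C).  Every node is perfused; blood convection
β·(T_blood − T_node) with β = ρc·V̇ (1.11 W/°C per L·h⁻¹) couples all
segments through the well-mixed blood pool.  There is no direct
segment-to-segment conduction.

Skin nodes lose dry heat to the operative temperature
T_op = (h_r·T_rad + h_c·T_air)/(h_r + h_c) through the regional total
thermal resistance, and latent heat ω·(P_sat(T_sk) − P_air)·A/R_e through
the regional total evaporative resistance.  Respiratory loss
q_resp = [0.0014·(34 − T_air) + 0.0173·(5.87 − P_air,kPa)]·M is charged to
the torso core.  Saturation vapor pressure uses the Antoine form over
water; the latent heat of sweat is 2430 J·g⁻¹.

### Clothing boundary resistances

Ensemble intrinsic resistance per region is the plain serial sum of the
selected items' regional intrinsic values (the bundled CSV is a
manikin-measured per-garment, per-region table, so no clothing-area factor
is applied by default; a per-layer area-factor hook exists and defaults to
1.0).  The surface air layer adds R_air = 1/(h_c + h_r) with
h_r = 4.7 W·m⁻²·°C⁻¹ and h_c = max(3.1, 8.3·√v); the evaporative air layer
follows from the Lewis relation (16.5 K·kPa⁻¹).  Only the air layer is
wind-corrected; intrinsic values are the 0.4 m·s⁻¹ manikin measurements.
A region counts as *covered* when its intrinsic thermal resistance exceeds
0.001 m²·°C/W, so trace spill-over cells in the garment table (e.g. a
trouser's 0.001 contribution outside its zone) do not mark a region
clothed.  The database schema has no slot column; each garment's selection
zone is inferred from the region carrying its largest thermal resistance.

### Control

Signals: the hypothalamic drive is the head-core deviation from set point;
the integrated skin signal is the area-weighted sum of regional skin
deviations (weights = area fractions, summing to 1).

* **Shivering** (W/m²): 19.4·(−core)₊·(−skin)₊ + 2.0·(−skin)₊, capped at
  90 W/m², distributed to muscle (torso 50 %, legs 30 %, arms 12 %, rest
  8 %).
* **Vasomotion**: per-region skin blood flow
  (basal + f_dil·DIL)/(1 + f_str·STR), clamped to regional min/max, with
  DIL = 75·(core)₊ + 0.2·(M − M_basal)₊ and
  STR = [15·(−core)₊ + 0.5·(−skin)₊ − 10·(core)₊ − 0.04·(M − M_basal)₊]₊.
  Deep (core/muscle/fat) hand and foot flows constrict with the same STR
  (weight 0.6, floor 0.02 L/h per node).
* **Sweating** (g/min, whole body): [30·(core)₊ + 5·(skin)₊ −
  2·(−skin)₊]₊, split by area fraction.  Regional wettedness is
  ω = 0.06 + (1 − 0.06)·E_sweat/E_max, clipped to [0.06, 1].

The two exercise terms shift the vasomotor thresholds at exercise onset,
before the core has warmed.  This is a deliberate design choice: with
core-driven control alone, the model's fingers transiently pass the 5 °C
limit in the first minutes of hard exercise at −30/−40 °C, whereas the
cold-chamber pattern this package mirrors is that exercising subjects kept
finger temperatures above the limit for the full exposure while resting
subjects did not.  Maintained extremity blood flow during exercise in cold
is well documented; representing it as a threshold shift keeps the
controller algebra linear in the signals.

### Reported variables

"Core temperature" reported to the metrics layer is the torso core (a
rectal surrogate, matching how validation studies instrument core
temperature); the hypothalamic drive remains the head core.  The hand and
foot skin nodes stand for finger and toe when the 5 °C criteria are
applied.  Mean skin temperature is the 6-region area-weighted average —
the multi-site weighting formulas used in human studies are not published
at regional resolution, so no attempt is made to mimic them.

## Thermoneutral calibration

The parameter file prescribes geometry fractions, capacities,
conductances, basal perfusion, control gains, and the core and skin
set-point anchors (torso/head core 37.0 °C; skin 32.8–34.8 °C, extremities
cooler).  The remaining basal quantities are *solved*, not hand-tuned: at
the documented thermoneutral environment (30 °C, 40 % RH, 0.1 m·s⁻¹, nude,
basal activity, ω = 0.06) the 24 node balances plus the blood balance form
a linear system in the muscle and fat temperatures (12), the muscle and
core basal metabolic heats (12), and the blood temperature (1).  One
linear solve therefore makes the initial state an exact fixed point of the
passive + active system; calibration fails loudly if any solved basal heat
is negative or any solved temperature is unphysical.  The calibrated
whole-body basal rate comes to ≈ 49 W/m² for the default adult (the 45
W/m² textbook default remains the activity-validation floor; pushing the
thermoneutral air temperature up to force 45 breaks the positivity of the
solved basal heats, so the calibrated value is kept and documented).

## Numerics

Fixed-step classical RK4, default Δt = 10 s (snapped to divide the 60-s
output grid), minute-sampled output, no randomness anywhere in the solver.
Step-halving changes trajectories by < 10⁻⁴ °C in the scenarios tested —
far inside the 0.05 °C acceptance band — because the fastest node time
constants (hand skin in strong wind) are still ≥ 100 s.  Three cumulative
energy integrals (metabolic + shivering, surface, respiratory) ride along
in the state vector, so the audit ΔH = E_met − E_surface − E_resp holds to
machine precision and the isolated-body conservation test is exact rather
than quadrature-limited.  Controller clamps (max(0,·), clips) make the
right-hand side only piecewise smooth; RK4 handles this without visible
artifacts at the default step.

## Endurance metrics

Threshold crossings are located by linear interpolation between minute
samples; a series that starts beyond its threshold reports 0 and one that
never crosses reports the beyond-horizon sentinel (∞, rendered as
"> horizon").  Exposed-skin endurance is the earliest 5 °C crossing among
regions with covered = false, simulated inside the same body model (a bare
region simply carries air-layer-only resistance); the head skin node
stands for the face when the head is bare.  Ties among limiting factors
break by severity: core > hand > foot > exposed > comfort.  The default
horizon is 480 min, and all thresholds are configurable (e.g. a 13–16 °C
hand threshold for manual-performance planning instead of injury
prevention).

## Wind-chill guidance

WCT = 13.12 + 0.6215·T + (0.3965·T − 11.37)·V^0.16 (T in °C, V in km/h),
defined as T itself below the 4.8 km/h validity floor.  The four-category
frostbite-time chart is bundled as data and consulted by nearest-cell
lookup with no interpolation, matching how such charts are used.  Because
the published chart's cell-by-cell shading could not be obtained offline,
the bundled grid is a synthetic reconstruction: categories are iso-WCT
bands (30 min ≤ −27.8 °C, 10 min ≤ −47.8 °C, 5 min ≤ −59.4 °C) calibrated
to two documented anchor cells (−32 °C at 2.2 m·s⁻¹ → 30 min; −17.8 °C at
6.7 m·s⁻¹ → 30 min).  The file is swappable for a transcription of any
chart edition with the same layout, and the chart tests (anchors,
monotonicity along both axes) apply to whatever file is bundled.

## Validation machinery and the synthetic cohort

RMSD = √(Σd²/n) on a 10-min comparison grid (predictions linearly
resampled; the grid spacing is fixed, the resampling rule is a
documented choice).  A prediction is valid when RMSD ≤ observed SD, with
the boundary counted valid, and an endpoint is "within band" when
|prediction − mean| ≤ SD, also closed — both conventions chosen to match
the inclusive "within mean ± SD" reading.  Comparisons default to the
observed *mean* trace (whether per-subject or mean traces were used
historically is not stated; both are accepted).

The synthetic generator adds independent Gaussian noise (per subject, per
time point) to a known truth trajectory and reports the across-subject
mean and SD.  It emulates between-subject spread only: real cohorts have
serially correlated, subject-specific offsets, drift, and occasional
sensor artifacts, none of which are modelled.  A green comparison test
therefore establishes that the RMSD/validity pipeline is implemented
correctly — not that the physiological model reproduces any particular
human dataset, which would require the unpublished time series.

## What the generator and tests do not establish

* The human-study figures (end-of-exposure temperatures, observed
  endurance times) are not numerically reproduced; the package asserts the
  qualitative pattern instead: resting fingers reach 5 °C before 120 min
  at ≤ −20 °C with times shrinking as air cools, exercising fingers do
  not, and exercise keeps hand skin warmer at every minute.
* Ambient monotonicity ("colder air never warms any node") holds for the
  passive + vasomotor system; with shivering active, working muscle is
  legitimately warmer in colder air, so the full-controls check is scoped
  to skin nodes and the reported core.

## Known limitations

* No counter-current heat exchange, no cold-induced vasodilation (CIVD)
  oscillations, no immersion, no moisture uptake by clothing (wet-
  insulation decay is proxied only by the wettedness-based comfort time).
* Conductances are fixed for a reference adult; only capacities and areas
  scale with the person.  Predictions for bodies far from 1.75 m / 75 kg
  should be treated cautiously.
* The garment table contains no handwear or footwear (all hand/foot cells
  ≈ 0), so database-built ensembles have effectively bare hands and feet;
  the bundled study scenarios add documented glove/boot stand-in
  resistances in expert mode.
* Guidance is population-typical, not individualized; no injury
  probability is estimated.
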