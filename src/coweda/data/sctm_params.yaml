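# Six-cylinder thermoregulatory model parameters.
#
# Every number the model uses is defined here; changing a value requires no
# code change.  Geometry and capacities are fractions scaled by the person's
# DuBois area and mass; conductances are absolute W/C for the reference
# adult.  Muscle- and fat-compartment set points plus the per-node basal
# metabolic distribution are *derived* at load time by solving the linear
# steady-state balance at the thermoneutral environment below, so that the
# initial state is an exact fixed point of the passive+active system.

segments: [head, torso, arm, leg, hand, foot]
compartments: [core, muscle, fat, skin]

# Fraction of DuBois surface area per segment (must sum to 1).
area_fraction:
  head: 0.07
  torso: 0.36
  arm: 0.14
  leg: 0.32
  hand: 0.05
  foot: 0.06

# Fraction of body mass per segment (must sum to 1).
mass_fraction:
  head: 0.070
  torso: 0.514
  arm: 0.120
  leg: 0.260
  hand: 0.012
  foot: 0.024

# Compartment mass split within each segment (rows sum to 1).
compartment_mass_split:
  head:  {core: 0.75, muscle: 0.10, fat: 0.075, skin: 0.075}
  torso: {core: 0.35, muscle: 0.45, fat: 0.14,  skin: 0.06}
  arm:   {core: 0.12, muscle: 0.63, fat: 0.15,  skin: 0.10}
  leg:   {core: 0.15, muscle: 0.63, fat: 0.14,  skin: 0.08}
  hand:  {core: 0.15, muscle: 0.35, fat: 0.25,  skin: 0.25}
  foot:  {core: 0.15, muscle: 0.35, fat: 0.25,  skin: 0.25}

# Tissue specific heats, J/kg/C.
specific_heat: {core: 3700.0, muscle: 3768.0, fat: 2510.0, skin: 3680.0}

# Central blood pool heat capacity (J/C) and the heat-carrying equivalent of
# blood flow (W/C per L/h; rho*c of blood / 3600).
blood_heat_capacity: 10000.0
blood_flow_heat_equiv: 1.11

# Radial conduction conductances, W/C per interface.
conduction:
  core_muscle: {head: 3.0, torso: 6.0, arm: 4.0, leg: 5.0, hand: 1.0, foot: 1.0}
  muscle_fat:  {head: 1.5, torso: 10.0, arm: 6.0, leg: 16.0, hand: 1.5, foot: 1.5}
  fat_skin:    {head: 2.0, torso: 17.0, arm: 6.0, leg: 10.0, hand: 1.6, foot: 1.6}

# Basal blood perfusion per node, L/h (thermally effective flows).
basal_blood_flow:
  core:   {head: 45.0, torso: 180.0, arm: 3.0, leg: 2.5, hand: 0.4, foot: 0.3}
  muscle: {head: 1.0,  torso: 15.0,  arm: 1.2, leg: 2.5, hand: 0.3, foot: 0.3}
  fat:    {head: 0.3,  torso: 1.0,   arm: 0.3, leg: 0.6, hand: 0.1, foot: 0.1}
  skin:   {head: 2.0,  torso: 4.0,   arm: 1.5, leg: 2.0, hand: 0.6, foot: 0.5}

# Thermoneutral anchors, C.  Core and skin temperatures are prescribed;
# muscle and fat temperatures are solved at calibration.
set_point_core: {head: 37.0, torso: 37.0, arm: 36.2, leg: 36.6, hand: 36.3, foot: 36.4}
set_point_skin: {head: 34.8, torso: 34.2, arm: 33.8, leg: 33.6, hand: 33.7, foot: 33.4}

# Basal metabolic heat fixed per unit mass for skin and fat nodes (W/kg);
# muscle and core basal heat are solved at calibration.
basal_met_skin_per_kg: 0.2
basal_met_fat_per_kg: 0.1

# Thermoneutral calibration environment (nude, near-still air).
thermoneutral:
  t_air: 30.0
  rh: 40.0
  v_wind: 0.1

# Respiratory heat loss q = [a*(34 - t_air) + b*(5.87 - P_air_kPa)] * M_total,
# applied to the torso core.
respiration_coefficients: [0.0014, 0.0173]

# --- Thermoregulatory control -------------------------------------------
# Integrated skin signal weights = area fractions; hypothalamic drive is the
# head-core temperature.

# Skin blood flow per region (L/h):
#   skbf = clamp((basal + frac_dil*DIL) / (1 + frac_str*STR), min, max)
#   DIL = g_dil * max(0, core_signal)
#   STR = max(0, g_str_core*(-core)+ + g_str_skin*(-skin)+ - g_str_inhib*(core)+
#             - g_str_exercise*(M - M_basal)+)
# The exercise term models the immediate rise of the vasoconstriction
# threshold at exercise onset (before the core has warmed).
vasomotor:
  g_dil: 75.0          # L/h per C warm core signal
  g_dil_exercise: 0.2  # L/h per W/m2 of metabolic rate above basal
  g_str_core: 15.0     # per C cold core signal
  g_str_skin: 0.5      # per C cold skin signal
  g_str_inhib: 10.0    # per C warm core signal (constriction release)
  g_str_exercise: 0.04 # per W/m2 of metabolic rate above basal
  frac_dil:  {head: 0.10, torso: 0.30, arm: 0.14, leg: 0.24, hand: 0.12, foot: 0.10}
  frac_str:  {head: 0.30, torso: 1.00, arm: 1.00, leg: 1.00, hand: 1.00, foot: 1.00}
  skbf_min:  {head: 1.0, torso: 0.8, arm: 0.3, leg: 0.4, hand: 0.04, foot: 0.04}
  skbf_max:  {head: 10.0, torso: 35.0, arm: 15.0, leg: 25.0, hand: 8.0, foot: 6.0}
  # Deep (core/muscle/fat) extremity flows constrict too:
  #   flow = max(basal / (1 + deep_str_frac*STR), deep_min)
  deep_str_frac: {head: 0.0, torso: 0.0, arm: 0.0, leg: 0.0, hand: 0.6, foot: 0.6}
  deep_min_flow: 0.02  # L/h per node

# Shivering (W/m2): g_prod*(-core)+*(-skin)+ + g_skin*(-skin)+, capped.
shivering:
  g_prod: 19.4
  g_skin: 2.0
  max_wm2: 90.0
  distribution: {head: 0.03, torso: 0.50, arm: 0.12, leg: 0.30, hand: 0.02, foot: 0.03}

# Sweating (g/min whole body): max(0, g_core*(core)+ + g_skin*(skin)+
#                                       - g_inhib*(-skin)+), split by area.
sweating:
  g_core: 30.0
  g_skin: 5.0
  g_inhib: 2.0

# Exercise heat (metabolic rate above basal) goes to muscle, split as below
# (treadmill walking pattern).
work_distribution: {head: 0.00, torso: 0.12, arm: 0.08, leg: 0.75, hand: 0.02, foot: 0.03}

# Extra muscle perfusion per W of local exercise/shivering heat, L/h per W.
work_perfusion: 0.30

# Skin wettedness floor (basal diffusion) and sweat latent heat, J/g.
wettedness_min: 0.06
latent_heat: 2430.0

# Integration defaults.
dt_seconds: 10.0
output_interval_seconds: 60.0
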