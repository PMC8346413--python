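# Mirror of validation study 1, resting trials at -30 C (M = 71 W/m2,
# v = 1.34 m/s, 120-min exposure limit).  Expert-mode resistances: the
# extreme-ensemble intrinsic sums plus documented stand-in values for the
# light-duty glove and vapor-barrier boot (absent from the bundled garment
# table), each plus the air layer at 1.34 m/s (R_air ~ 0.070 m2.C/W).
label: study-1 rest -30 C
environment: {t_air: -30.0, rh: 25.0, v_wind: 1.34}
activity: rest
duration: 120
resistances:
  thermal:      {head: 0.223, torso: 0.998, arm: 0.899, leg: 0.605, hand: 0.140, foot: 0.320}
  evaporative:  {head: 36.2, torso: 109.2, arm: 113.3, leg: 93.7, hand: 21.3, foot: 31.3}
  covered:      {head: true, torso: true, arm: true, leg: true, hand: true, foot: true}
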