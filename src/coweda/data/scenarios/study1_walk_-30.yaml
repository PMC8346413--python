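# Mirror of validation study 1, treadmill-exercise trials at -30 C
# (M = 171 W/m2, v = 1.34 m/s).
label: study-1 walk -30 C
environment: {t_air: -30.0, rh: 25.0, v_wind: 1.34}
activity: walk
duration: 120
resistances:
  thermal:      {head: 0.223, torso: 0.998, arm: 0.899, leg: 0.605, hand: 0.140, foot: 0.320}
  evaporative:  {head: 36.2, torso: 109.2, arm: 113.3, leg: 93.7, hand: 21.3, foot: 31.3}
  covered:      {head: true, torso: true, arm: true, leg: true, hand: true, foot: true}
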