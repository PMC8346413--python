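# Mirror of validation study 2: seated rest at ~0.5 C, RH 51%, 1.34 m/s,
# 120 min, three torso layers, two leg layers, fleece hat, bare hands.
label: study-2 rest 0.5 C bare hands
environment: {t_air: 0.5, rh: 51.0, v_wind: 1.34}
activity: rest
duration: 120
ensemble:
  - Gen III ECWCS lightweight cold weather undershirt
  - Gen III ECWCS lightweight cold weather drawers
  - Gen III ECWCS fleece cold weather jacket
  - Gen III ECWCS soft shell jacket
  - Gen III ECWCS soft shell trouser
extra_intrinsic:
  # fleece hat and cold-wet boot stand-ins (not in the bundled garment table)
  thermal: {head: 0.10, foot: 0.25}
  evaporative: {head: 12.0, foot: 28.0}
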