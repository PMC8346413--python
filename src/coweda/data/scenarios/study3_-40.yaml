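# Mirror of validation study 3: 120 min at -40 C, mostly seated with brief
# walking bouts; modelled at the resting rate.  Extreme ensemble plus
# balaclava/mitten/vapor-barrier-boot stand-ins.
label: study-3 rest -40 C
environment: {t_air: -40.0, rh: 50.0, v_wind: 1.34}
activity: rest
duration: 120
ensemble_preset: extreme
extra_intrinsic:
  thermal: {head: 0.08, hand: 0.25, foot: 0.30}
  evaporative: {head: 10.0, hand: 30.0, foot: 35.0}
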