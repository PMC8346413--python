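# The guidance-comparison condition: -32 C air at 2.2 m/s wind, resting,
# moderate preset; exposed-skin endurance contrasts with the chart's 30-min
# frostbite category.
label: WCT comparison -32 C, 2.2 m/s
environment: {t_air: -32.0, rh: 50.0, v_wind: 2.2}
activity: rest
duration: 120
ensemble_preset: moderate
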