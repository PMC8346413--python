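# Named ensemble presets assembled from the bundled GEN III ECWCS database.
# The mild/moderate/extreme presets are documented stand-ins for typical
# cold-weather gear levels; no equivalence to any particular fielded preset
# is claimed.
mild:
  - Gen III ECWCS lightweight cold weather undershirt
  - Gen III ECWCS lightweight cold weather drawers
  - Gen III ECWCS cold weather wind jacket
moderate:
  - Gen III ECWCS lightweight cold weather undershirt
  - Gen III ECWCS lightweight cold weather drawers
  - Gen III ECWCS midweight cold weather shirt
  - Gen III ECWCS midweight cold weather drawers
  - Gen III ECWCS fleece cold weather jacket
  - Gen III ECWCS soft shell jacket
  - Gen III ECWCS soft shell trouser
extreme:
  - Gen III ECWCS lightweight cold weather undershirt
  - Gen III ECWCS lightweight cold weather drawers
  - Gen III ECWCS midweight cold weather shirt
  - Gen III ECWCS midweight cold weather drawers
  - Gen III ECWCS fleece cold weather jacket
  - Gen III ECWCS extreme cold weather parka (freed hood)
  - Gen III ECWCS extreme cold weather trouser
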