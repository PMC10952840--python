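# Default applicability rules for the 30-character floral schema.
# A rule fires when the trigger character is observed at the trigger state;
# the listed characters are then inapplicable (treated as missing in
# distances). Replace this file to use a different rule set.
rules:
  - trigger: {character: perianth_presence, state: 0}
    inapplicable:
      - perianth_phyllotaxis
      - perianth_merism
      - perianth_whorls
      - perianth_differentiation
      - perianth_fusion
      - perianth_spurs
      - androecium_perianth_fusion
  - trigger: {character: perianth_differentiation, state: 0}
    inapplicable: [perianth_spurs]
  - trigger: {character: carpel_number, state: 0}
    inapplicable: [carpel_fusion]
  - trigger: {character: stamen_number, state: 0}
    inapplicable: [stamen_fusion, androecium_whorls]
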