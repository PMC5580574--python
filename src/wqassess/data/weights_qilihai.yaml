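# Expert-elicited AHP weights for the eight-indicator assessment
# (pollution and biological indicators weighted above general ones).
weights:
  pH: 0.036
  DO: 0.107
  transparency: 0.107
  COD: 0.178
  TN: 0.178
  TP: 0.178
  petroleum: 0.059
  chlorophyll_a: 0.157
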