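# Default standards set for the eight-indicator wetland assessment.
#
# first_class_value is the Coi used to standardize each indicator (the
# class-I target a national nature reserve must meet).  class_limits are the
# five surface-water quality classes of GB3838-2002 (mg/L unless noted);
# for TN and TP the lake/reservoir columns are bundled as the default
# because the study area is a lagoon-type lake wetland — these columns make
# the TN (0.2) and TP (0.01) targets coincide with class I, which the river
# columns do not.  The river TP column is kept under alt_class_limits for
# users assessing flowing waters.  Transparency and chlorophyll-a have no
# class table in GB3838-2002; their first-class targets follow common
# practice for reserve-grade clarity and phytoplankton biomass, and
# single-factor evaluation for them reports first-class compliance only.
indicators:
  pH:
    units: ""
    direction: range
    category: general
    first_class_value: [6.0, 9.0]
  DO:
    units: mg/L
    direction: benefit
    category: general
    first_class_value: 7.5
    class_limits: {I: 7.5, II: 6.0, III: 5.0, IV: 3.0, V: 2.0}
  transparency:
    units: m
    direction: benefit
    category: general
    first_class_value: 5.0
  COD:
    units: mg/L
    direction: pollutant
    category: pollution
    first_class_value: 15.0
    class_limits: {I: 15.0, II: 15.0, III: 20.0, IV: 30.0, V: 40.0}
  TN:
    units: mg/L
    direction: pollutant
    category: pollution
    first_class_value: 0.2
    class_limits: {I: 0.2, II: 0.5, III: 1.0, IV: 1.5, V: 2.0}
  TP:
    units: mg/L
    direction: pollutant
    category: pollution
    first_class_value: 0.01
    class_limits: {I: 0.01, II: 0.025, III: 0.05, IV: 0.1, V: 0.2}
    alt_class_limits:
      river: {I: 0.02, II: 0.1, III: 0.2, IV: 0.3, V: 0.4}
  petroleum:
    units: mg/L
    direction: pollutant
    category: pollution
    first_class_value: 0.05
    class_limits: {I: 0.05, II: 0.05, III: 0.05, IV: 0.5, V: 1.0}
  chlorophyll_a:
    units: mg/L
    direction: pollutant
    category: biological
    first_class_value: 0.002
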