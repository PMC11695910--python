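# Synthetic beta-lactam-like reference compound. All values are frozen test
# scaffolding, not estimates of any real drug.
kind: compound
key: synthecillin
compound_name: synthecillin
model:
  n_compartments: 2
  typical_params:
    CL: 8.0       # L/h at the reference CrCL
    V1: 15.0      # L
    Q2: 6.0       # L/h
    V2: 25.0      # L
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.09, 0.018]   # log-scale variances; 30% CV on CL, corr 0.3
      - [0.018, 0.04]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 80.0
      exponent_or_slope: 0.75
penetration:
  fu: 0.6
  fu_low: 0.5
  fu_high: 0.7
  tpr:
    ELF: {value: 0.5, low: 0.4, high: 0.6, provenance: measured}
    peritoneal: {value: 0.8, low: 0.7, high: 0.9, provenance: measured}
    prostate: {value: 0.2, low: 0.15, high: 0.25, provenance: measured}
target:
  metric: ft_above_mic
  tier_magnitudes: {EUCAST: 40.0, Severe: 60.0, Aggressive: 90.0}
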