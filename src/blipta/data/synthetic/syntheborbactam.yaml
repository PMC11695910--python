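# Synthetic AUC-driven inhibitor-like reference compound (fAUC0-24/MIC target).
kind: compound
key: syntheborbactam
compound_name: syntheborbactam
model:
  n_compartments: 2
  typical_params:
    CL: 10.0
    V1: 10.0
    Q2: 4.0
    V2: 12.0
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.09, 0.0]
      - [0.0, 0.04]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 80.0
      exponent_or_slope: 0.8
penetration:
  fu: 0.7
  tpr:
    ELF: {value: 0.6, provenance: measured}
    peritoneal: {value: 0.9, provenance: measured}
    prostate: {value: 0.18, provenance: measured}
target:
  metric: fauc_over_mic
  tier_magnitudes: {EUCAST: 20.0, Severe: 35.0, Aggressive: 50.0}
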