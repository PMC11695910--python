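# Piperacillin (BL, partner of tazobactam; patient-data source model, hence
# the wider interindividual variability).
kind: compound
key: piperacillin
compound_name: piperacillin
model:
  n_compartments: 2
  typical_params:
    CL: 13.0     # L/h at CrCL 100 mL/min
    V1: 12.0
    Q2: 10.0
    V2: 8.0
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.20, 0.0]      # ~46% CV on CL
      - [0.0, 0.10]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 100.0
      exponent_or_slope: 0.8
penetration:
  fu: 0.70
  tpr:
    ELF: {value: 0.49, provenance: measured}
    peritoneal: {value: 0.75, provenance: measured}
    prostate: {value: 0.36, low: 0.35, high: 0.37, provenance: measured}
target:
  metric: ft_above_mic
  tier_magnitudes: {EUCAST: 40.0, Severe: 70.0, Aggressive: 100.0}
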