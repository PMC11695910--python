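# Meropenem (BL, partner of vaborbactam; joint source model).
kind: compound
key: meropenem
compound_name: meropenem
model:
  n_compartments: 2
  typical_params:
    CL: 14.5     # L/h at CrCL 100 mL/min
    V1: 10.5
    Q2: 15.0
    V2: 4.5
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.09, 0.0]
      - [0.0, 0.09]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 100.0
      exponent_or_slope: 0.75
penetration:
  fu: 0.98
  tpr:
    ELF: {value: 0.65, provenance: measured}
    peritoneal: {value: 0.92, provenance: measured}
    prostate: {value: 0.15, provenance: measured}
target:
  metric: ft_above_mic
  tier_magnitudes: {EUCAST: 45.0, Severe: 70.0, Aggressive: 100.0}
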