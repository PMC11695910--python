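# Imipenem (BL, partner of relebactam; joint source model). Prostate
# penetration is unknown: prostatitis cells omitted.
kind: compound
key: imipenem
compound_name: imipenem
model:
  n_compartments: 2
  typical_params:
    CL: 13.0     # L/h at CrCL 100 mL/min
    V1: 11.0
    Q2: 7.0
    V2: 6.0
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.10, 0.0]
      - [0.0, 0.06]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 100.0
      exponent_or_slope: 0.7
penetration:
  fu: 0.80
  tpr:
    ELF: {value: 0.55, provenance: measured}
    peritoneal: {value: 0.82, provenance: measured}
    # prostate: unknown
target:
  metric: ft_above_mic
  tier_magnitudes: {EUCAST: 6.5, Severe: 15.0, Aggressive: 35.0}
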