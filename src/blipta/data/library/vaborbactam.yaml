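# Vaborbactam (BLI, AUC-driven). Peritoneal and prostate TPRs are inherited
# from meropenem by the BL->BLI extrapolation rule at load time.
kind: compound
key: vaborbactam
compound_name: vaborbactam
model:
  n_compartments: 2
  typical_params:
    CL: 10.8     # L/h at CrCL 100 mL/min
    V1: 9.0
    Q2: 5.0
    V2: 9.6
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.09, 0.0]
      - [0.0, 0.06]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 100.0
      exponent_or_slope: 0.8
penetration:
  fu: 0.67
  tpr:
    ELF: {value: 0.79, provenance: measured}
    # peritoneal, prostate: extrapolated from meropenem at load
target:
  metric: fauc_over_mic
  tier_magnitudes: {EUCAST: 35.0, Severe: 50.0, Aggressive: 65.0}
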