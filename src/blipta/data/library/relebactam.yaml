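# Relebactam (BLI, AUC-driven, fAUC0-24/MIC target). The peritoneal TPR is
# inherited from imipenem by the BL->BLI extrapolation rule at load time;
# prostate is unknown for both compounds, so those cells are omitted.
kind: compound
key: relebactam
compound_name: relebactam
model:
  n_compartments: 2
  typical_params:
    CL: 9.0      # L/h at CrCL 100 mL/min
    V1: 10.5
    Q2: 6.0
    V2: 7.5
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
      exponent_or_slope: 0.79
penetration:
  fu: 0.78
  tpr:
    ELF: {value: 0.54, provenance: measured}
    # peritoneal: extrapolated from imipenem at load
    # prostate: unknown
target:
  metric: fauc_over_mic
  tier_magnitudes: {EUCAST: 5.2, Severe: 8.0, Aggressive: 12.0}
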