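# Avibactam (BLI, time-dependent, %fT>C_T target with C_T = 1 mg/L).
# PopPK values are a provisional transcription from the pooled source model.
# The peritoneal TPR is the published extrapolation from ceftazidime.
kind: compound
key: avibactam
compound_name: avibactam
model:
  n_compartments: 2
  typical_params:
    CL: 11.0     # L/h at CrCL 100 mL/min (predominantly renal elimination)
    V1: 8.0
    Q2: 10.0
    V2: 14.0
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.09, 0.0]
      - [0.0, 0.04]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 100.0
      exponent_or_slope: 0.95
penetration:
  fu: 0.92
  tpr:
    ELF: {value: 0.30, provenance: measured}
    peritoneal: {value: 0.33, provenance: extrapolated}
    prostate: {value: 0.15, provenance: extrapolated}
target:
  metric: ft_above_ct
  c_t_mg_per_L: 1.0
  tier_magnitudes: {EUCAST: 50.0, Severe: 75.0, Aggressive: 100.0}
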