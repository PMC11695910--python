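# Ceftazidime (BL, partner of avibactam). PopPK values are a provisional
# transcription from the pooled phase I-III source model; verify against the
# original publication before relying on absolute PTA values.
kind: compound
key: ceftazidime
compound_name: ceftazidime
model:
  n_compartments: 2
  typical_params:
    CL: 6.5      # L/h at CrCL 100 mL/min
    V1: 11.5     # L
    Q2: 6.5      # L/h
    V2: 6.0      # L
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.0625, 0.0]    # ~25% CV on CL; source correlations not transcribed
      - [0.0, 0.04]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 100.0
      exponent_or_slope: 0.85
penetration:
  fu: 0.90
  tpr:
    ELF: {value: 0.30, provenance: measured}
    peritoneal: {value: 0.34, low: 0.33, high: 0.35, provenance: measured}
    prostate: {value: 0.15, provenance: measured}
target:
  metric: ft_above_mic
  tier_magnitudes: {EUCAST: 50.0, Severe: 75.0, Aggressive: 100.0}
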