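# Ceftolozane (BL, partner of tazobactam). Prostate penetration is unknown:
# prostatitis cells for this compound (and the combination) are omitted, never
# imputed. PopPK values are a provisional transcription from the source model.
kind: compound
key: ceftolozane
compound_name: ceftolozane
model:
  n_compartments: 2
  typical_params:
    CL: 5.1      # L/h at CrCL 109 mL/min (source model reference)
    V1: 11.0
    Q2: 1.6
    V2: 2.6
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.10, 0.0]
      - [0.0, 0.06]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 109.0
      exponent_or_slope: 0.72
penetration:
  fu: 0.815
  fu_low: 0.79
  fu_high: 0.84
  tpr:
    ELF: {value: 0.50, provenance: measured}
    peritoneal: {value: 0.74, provenance: measured}
    # prostate: unknown
target:
  metric: ft_above_mic
  tier_magnitudes: {EUCAST: 30.0, Severe: 45.0, Aggressive: 60.0}
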