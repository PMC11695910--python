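# Tazobactam as dosed with ceftolozane (the joint source model and the TPR
# values measured for that combination). The distinct entry dosed with
# piperacillin lives in tazobactam_pip.yaml; the loader's swap option
# exchanges ELF/peritoneal TPRs between the two for the swap analysis.
kind: compound
key: tazobactam_cet
compound_name: tazobactam
model:
  n_compartments: 2
  typical_params:
    CL: 18.0     # L/h at CrCL 109 mL/min
    V1: 14.2
    Q2: 3.8
    V2: 4.0
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.16, 0.0]      # ~40% CV on CL
      - [0.0, 0.09]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 109.0
      exponent_or_slope: 0.8
penetration:
  fu: 0.70
  tpr:
    ELF: {value: 0.62, provenance: measured}
    peritoneal: {value: 0.95, provenance: measured}
    prostate: {value: 0.34, low: 0.31, high: 0.37, provenance: measured}
target:
  metric: ft_above_ct
  c_t_mg_per_L: 1.0
  tier_magnitudes: {EUCAST: 20.0, Severe: 30.0, Aggressive: 45.0}
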