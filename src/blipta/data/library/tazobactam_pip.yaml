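# Tazobactam as dosed with piperacillin (separate source model; patient data).
# The EUCAST-tier 40% fT>C_T magnitude is the published extrapolation (the
# rationale document leaves the time fraction unspecified).
kind: compound
key: tazobactam_pip
compound_name: tazobactam
model:
  n_compartments: 2
  typical_params:
    CL: 12.0     # L/h at CrCL 100 mL/min
    V1: 10.0
    Q2: 4.0
    V2: 4.0
  iiv:
    parameters: [CL, V1]
    matrix:
      - [0.16, 0.0]
      - [0.0, 0.09]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 100.0
      exponent_or_slope: 0.8
penetration:
  fu: 0.70
  tpr:
    ELF: {value: 1.21, provenance: measured}
    peritoneal: {value: 0.79, provenance: measured}
    prostate: {value: 0.34, low: 0.31, high: 0.37, provenance: measured}
target:
  metric: ft_above_ct
  c_t_mg_per_L: 1.0
  tier_magnitudes: {EUCAST: 40.0, Severe: 70.0, Aggressive: 100.0}
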