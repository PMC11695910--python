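# Synthetic time-dependent inhibitor-like reference compound (%fT>C_T target).
# The missing peritoneal TPR exercises the BL->BLI extrapolation rule; the
# covariate cap exercises declared CrCL ceilings.
kind: compound
key: synthebactam
compound_name: synthebactam
model:
  n_compartments: 1
  typical_params:
    CL: 12.0
    V1: 18.0
  iiv:
    parameters: [CL]
    matrix:
      - [0.16]
  covariate_relations:
    - parameter: CL
      covariate: CRCL
      form: power
      reference_value: 80.0
      exponent_or_slope: 0.9
      covariate_cap: 150.0
penetration:
  fu: 0.9
  tpr:
    ELF: {value: 0.4, provenance: measured}
target:
  metric: ft_above_ct
  c_t_mg_per_L: 1.0
  tier_magnitudes: {EUCAST: 30.0, Severe: 50.0, Aggressive: 70.0}
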