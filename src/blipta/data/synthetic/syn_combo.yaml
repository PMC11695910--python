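# Synthetic fixed co-formulated combination over the reference compounds.
kind: combination
name: SYN
bl: synthecillin
bli: synthebactam
co_formulated: true
mic_grid_mg_per_L: [1.0, 2.0, 4.0, 8.0]
regimens:
  cIAI:
    bl: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 1.0, interval_h: 8.0}
  HAP/VAP:
    bl: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 1.0, interval_h: 8.0}
  cUTI:
    bl: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 1.0, interval_h: 8.0}
  bacteraemia:
    bl: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 1.0, interval_h: 8.0}
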