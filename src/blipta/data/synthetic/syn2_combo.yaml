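# Second synthetic combination: exercises the fAUC0-24/MIC attainment path.
kind: combination
name: SYN2
bl: synthecillin
bli: syntheborbactam
co_formulated: true
mic_grid_mg_per_L: [0.5, 1.0, 2.0, 4.0]
regimens:
  cIAI:
    bl: {dose_mg: 1000.0, infusion_duration_h: 0.5, interval_h: 12.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 12.0}
  HAP/VAP:
    bl: {dose_mg: 1000.0, infusion_duration_h: 0.5, interval_h: 12.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 12.0}
  bacteraemia:
    bl: {dose_mg: 1000.0, infusion_duration_h: 0.5, interval_h: 12.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 12.0}
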