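# Ceftolozane-tazobactam: 1 g / 0.5 g q8h (1 h infusion) for cIAI and cUTI;
# 2 g / 1 g q8h for HAP/VAP (EMA SmPC). Bacteraemia associated with the
# non-pneumonia indications uses the 1 g / 0.5 g regimen.
kind: combination
name: CET-TAZ
bl: ceftolozane
bli: tazobactam_cet
co_formulated: true
prostatitis_from: cUTI
mic_grid_mg_per_L: [0.5, 1.0, 2.0, 4.0]
regimens:
  cIAI:
    bl: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 1.0, interval_h: 8.0}
  HAP/VAP:
    bl: {dose_mg: 2000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
  cUTI:
    bl: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 1.0, interval_h: 8.0}
  bacteraemia:
    bl: {dose_mg: 1000.0, infusion_duration_h: 1.0, interval_h: 8.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 1.0, interval_h: 8.0}
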