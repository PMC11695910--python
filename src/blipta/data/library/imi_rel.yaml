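# Imipenem-relebactam: 500 mg / 250 mg every 6 h as a 30 min infusion
# (EMA SmPC). Prostate penetration unknown for both compounds, so the implicit
# prostatitis indication yields no resolvable cells.
kind: combination
name: IMI-REL
bl: imipenem
bli: relebactam
co_formulated: true
prostatitis_from: cUTI
mic_grid_mg_per_L: [0.25, 0.5, 1.0, 2.0]
regimens:
  cIAI:
    bl: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 6.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 0.5, interval_h: 6.0}
  HAP/VAP:
    bl: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 6.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 0.5, interval_h: 6.0}
  cUTI:
    bl: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 6.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 0.5, interval_h: 6.0}
  bacteraemia:
    bl: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 6.0}
    bli: {dose_mg: 250.0, infusion_duration_h: 0.5, interval_h: 6.0}
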