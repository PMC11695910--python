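# Piperacillin-tazobactam: 4 g / 0.5 g as a 30 min infusion; every 6 h for
# HAP/VAP (severe infection dosing) and every 8 h otherwise (EMA SmPC).
kind: combination
name: PIP-TAZ
bl: piperacillin
bli: tazobactam_pip
co_formulated: true
prostatitis_from: cUTI
mic_grid_mg_per_L: [1.0, 2.0, 4.0, 8.0]
regimens:
  cIAI:
    bl: {dose_mg: 4000.0, infusion_duration_h: 0.5, interval_h: 8.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 8.0}
  HAP/VAP:
    bl: {dose_mg: 4000.0, infusion_duration_h: 0.5, interval_h: 6.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 6.0}
  cUTI:
    bl: {dose_mg: 4000.0, infusion_duration_h: 0.5, interval_h: 8.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 8.0}
  bacteraemia:
    bl: {dose_mg: 4000.0, infusion_duration_h: 0.5, interval_h: 8.0}
    bli: {dose_mg: 500.0, infusion_duration_h: 0.5, interval_h: 8.0}
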