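# Meropenem-vaborbactam: 2 g / 2 g every 8 h as a 3 h infusion (EMA SmPC,
# all approved indications).
kind: combination
name: MER-VAB
bl: meropenem
bli: vaborbactam
co_formulated: true
prostatitis_from: cUTI
mic_grid_mg_per_L: [1.0, 2.0, 4.0, 8.0]
regimens:
  cIAI:
    bl: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
    bli: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
  HAP/VAP:
    bl: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
    bli: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
  cUTI:
    bl: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
    bli: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
  bacteraemia:
    bl: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
    bli: {dose_mg: 2000.0, infusion_duration_h: 3.0, interval_h: 8.0}
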