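{
  "kcat_m": 0.065,
  "KM_70": 1.0,
  "K70": 0.26,
  "S70_total": 30.0,
  "E_total": 400.0,
  "kd_m": 6.6,
  "KM_m": 8000.0,
  "kcat_p": 0.006,
  "KM_R": 10.0,
  "R_total": 1100.0,
  "k_mat": 0.0012,
  "Cm": 10.0,
  "Cp": 2.5,
  "Lm": 750.0,
  "P70": 0.0
}
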