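{
  "k_f": 2.7,
  "J_ER": 0.00085,
  "gamma": 7,
  "c_t": 2,
  "V_s": 1.5,
  "K_s": 0.15,
  "K1": 0.13,
  "K2": 1.05,
  "K3": 0.943,
  "K4": 0.145,
  "K5": 0.082,
  "k_m2": 0.21,
  "k_m4": 0.029,
  "V_0": 0.15,
  "V_Q": 7.82,
  "K_Q": 0.0086,
  "K_ip3k": 0.6,
  "K_PLC": 0.01,
  "k_3k": 1.5,
  "k_5p": 0.01,
  "k_a": 0.35,
  "k_b": 2.2,
  "PLC_tot": 1,
  "k_c": 0.33,
  "k_d": 2.17,
  "delta": 0.01,
  "V_R": 7.4,
  "K_R": 4467,
  "G_tot": 1
}
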