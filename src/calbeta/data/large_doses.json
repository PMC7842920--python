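{
  "k_f": 3.5,
  "J_ER": 0.0009,
  "gamma": 8.5,
  "c_t": 2,
  "V_s": 1.7,
  "K_s": 0.14,
  "K1": 0.21,
  "K2": 0.021,
  "K3": 0.943,
  "K4": 0.25,
  "K5": 0.01,
  "k_m2": 0.012,
  "k_m4": 0.00006,
  "V_0": 0.19,
  "V_Q": 380,
  "K_Q": 0.0086,
  "K_ip3k": 1.6,
  "K_PLC": 0.016,
  "k_3k": 0.7,
  "k_5p": 0.005,
  "k_a": 0.75,
  "k_b": 2,
  "PLC_tot": 1,
  "k_c": 0.047,
  "k_d": 4.7,
  "delta": 0.012,
  "V_R": 10,
  "K_R": 2000,
  "G_tot": 1
}
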