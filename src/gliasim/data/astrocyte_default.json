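{
  "r_ER_cyt": 0.185,
  "v_IP3R": 0.006,
  "Kd_IP3_1": 0.13,
  "Kd_IP3_2": 0.9434,
  "Kd_act": 0.08234,
  "Kd_inh": 1.049,
  "k_IP3R": 0.0002,
  "v_SERCA": 0.0009,
  "Km_SERCA": 0.1,
  "v_L": 0.00011,
  "Ca_tot": 2.0,
  "IP3_0": 0.16,
  "tau_IP3": 7142.0,
  "delta_IP3": 0.0002,
  "SIC_th": 196.69,
  "SIC_scale": 1.0,
  "noise_sd": 0.0
}
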