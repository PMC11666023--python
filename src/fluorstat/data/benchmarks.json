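{
  "conditions": {
    "n_total": 100000,
    "area_cm2": 1e-4,
    "surface_density_cm2": 1e9,
    "shots": 10,
    "per_fluorophore": {
      "FITC":          {"flux": 3.53e22, "t_int_cw": 1e-7,   "t_int_tg": 1.9e-8,  "gate_delay": 1e-9},
      "[Ru(bpy)3]Br2": {"flux": 1.28e21, "t_int_cw": 2e-5,   "t_int_tg": 4.75e-6, "gate_delay": 2.5e-7},
      "Eu3+L2":        {"flux": 9.43e17, "t_int_cw": 1.5e-2, "t_int_tg": 4.75e-3, "gate_delay": 2.5e-4},
      "EGFP":          {"flux": 8.48e22, "t_int_cw": 7.5e-8, "t_int_tg": 1.4e-8,  "gate_delay": 1e-9}
    }
  },
  "reference": {
    "FITC":          {"r_x": 1.22e7, "n_g": 95238, "n_e": 4762, "F_ph_areal": 9.96e15, "tau_ph_ns": 3.91,   "n_ph_cw": 95741, "n_ph_tg": 31792},
    "[Ru(bpy)3]Br2": {"r_x": 5.95e4, "n_g": 95238, "n_e": 4762, "F_ph_areal": 3.57e12, "tau_ph_ns": 800.00, "n_ph_cw": 6857,  "n_ph_tg": 2208},
    "Eu3+L2":        {"r_x": 67.84,  "n_g": 95238, "n_e": 4762, "F_ph_areal": 1.34e10, "tau_ph_ns": 7.02e5, "n_ph_cw": 19123, "n_ph_tg": 7010},
    "EGFP":          {"r_x": 1.76e7, "n_g": 95238, "n_e": 4762, "F_ph_areal": 1.02e16, "tau_ph_ns": 2.66,   "n_ph_cw": 73810, "n_ph_tg": 19856}
  },
  "flux_chain_inconsistent": ["Eu3+L2"]
}
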