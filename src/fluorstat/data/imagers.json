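{
  "benchmark": {
    "pixels": 100,
    "emission_coupling": 0.01,
    "excitation_coupling": 0.01,
    "qe_emission": 0.45,
    "qe_excitation": 0.45,
    "read_noise": 2.0,
    "dark_current": 5.0,
    "well_capacity": 50000.0,
    "filter_od": 6.0,
    "excitation_tail": 5e-8
  }
}
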