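{
  "50C": {
    "k_on": 55000.0,
    "k_off": 38000.0,
    "concentration": 1e-9,
    "strand_count": 1,
    "temperature": 50.0
  },
  "10C": {
    "k_on": 17000.0,
    "k_off": 200.0,
    "concentration": 1e-9,
    "strand_count": 1,
    "temperature": 10.0
  }
}
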