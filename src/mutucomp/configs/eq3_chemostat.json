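{
  "model": "chemostat",
  "operation": {
    "simulate": {}
  },
  "params": {
    "k10": 200.0,
    "k12": 200.0,
    "k20": 200.0,
    "k21": 200.0,
    "mu1": 1600.0,
    "mu2": 1600.0,
    "nu01": -1.0,
    "nu02": -1.0,
    "nu11": 0.2,
    "nu12": -0.1,
    "nu21": -0.1,
    "nu22": 0.2,
    "phi": 2.0,
    "s0_in": 50.0,
    "s1_in": 1.0,
    "s2_in": 1.0
  },
  "seed": 0
}
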