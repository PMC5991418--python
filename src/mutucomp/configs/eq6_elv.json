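{
  "model": "elv",
  "operation": {
    "fixedpoints": {}
  },
  "params": {
    "a1": 50.0,
    "a2": 50.0,
    "b11": 5.0,
    "b12": 10.0,
    "b21": 10.0,
    "b22": 5.0,
    "c1": 0.2,
    "c2": 0.2,
    "d": 2.0,
    "r1": 0.027,
    "r2": 0.027
  },
  "seed": 0
}
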