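{
  "num": [33.37, -96.47, 120.6, -80.08, 20.9, 1.71, 0.0, 0.0],
  "den": [1.0, -2.42, 2.72, -1.79, 0.45, 0.37, -0.68, 0.54, -0.17],
  "domain": "z",
  "Ts": 1.0
}
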