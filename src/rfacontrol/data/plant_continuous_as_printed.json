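{
  "num": [32.43, 135.0, 510.3, 925.7, 1104.0, 829.7, 556.9, 58.83, 0.81],
  "den": [1.0, 2.12, 15.76, 21.61, 55.28, 46.8, 49.14, 24.45, 7.28, 0.5],
  "domain": "s",
  "Ts": null
}
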