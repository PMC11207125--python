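{
  "num": [32.43, 135.0, 510.3, 925.7, 1104.0, 829.7, 556.9, 58.83, 0.81],
  "den": [1.0, 2.1186, 15.7632, 21.6147, 55.2829, 46.7952, 49.1387, 24.4473, 7.278, 0.5032],
  "domain": "s",
  "Ts": null
}
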