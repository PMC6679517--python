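{
  "epsilon": 2.0,
  "off": {
    "mu": [53.11, -76.8, 22.81, 2.34, -26.25, -9.45, -2.47, -98.0, 4.88, -68.36],
    "delta": [19.82, 112.8, 51.29, 45.95, 57.44, 54.45, 29.67, 77.87, 24.0, 37.81]
  },
  "on": {
    "mu": [-7.27, 32.13, 8.23, 74.03, -7.99, 5.7, 50.0, 18.7, 120.0, -3.5],
    "delta": [162.78, 68.21, 52.75, 33.85, 39.12, 31.11, 61.04, 32.84, 33.71, 107.32]
  }
}
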