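{
  "let_weighted": {
    "kappa": 0.055
  },
  "mcnamara": {
    "z1": 0.99064,
    "z2": 0.35605,
    "z3": 1.1012,
    "z4": 0.00387
  },
  "mm": {
    "a": 0.1966,
    "b": 0.008,
    "c": 0.0736,
    "d": 1.149,
    "e": 24.1,
    "f": 4.879e-4,
    "g": 2.84e-3,
    "h": 5.13e-2,
    "gamma_r": 1.726,
    "gamma_m": 0.0427
  },
  "uncertainty_pct": {
    "z1": 1.4, "z2": 4.2, "z3": 0.5, "z4": 23.6,
    "a": 0.4, "b": 3.4, "c": 0.2, "d": 1.0, "e": 0.6,
    "f": 0.8, "g": 4.7, "h": 1.6, "gamma_r": 2.0, "gamma_m": 16.7
  }
}
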