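{
  "name": "akt",
  "notes": "Minimal dimensionless insulin/AKT model: x1 = pAKT, x2 = pIRS, insulin input lam. Michaelis-Menten activation/deactivation of AKT makes the x1 balance rational; the dimensionless activation gain is k2*E2/k1 (the printed 909/1000 rate constants cancel), which reproduces the published basis coefficients exactly.",
  "variables": ["x1", "x2"],
  "parameters": {"k1": "0.909", "k2": "0.909", "beta": "1", "delta": "1",
                 "E2": "1", "K1": "0.05", "K2": "0.05", "theta": "0.99",
                 "lam": "0.4"},
  "odes": {
    "x1": "-beta*x1*x2/(K1 + x1) + (k2/k1)*E2*(1 - x1)/(K2 + (1 - x1))",
    "x2": "(delta/beta)*(k2/k1)*E2*lam + theta*(1 - x1) - delta*x2"
  },
  "order": ["x2", "x1"],
  "outputs": ["x1"],
  "scan": {"parameter": "lam", "lo": 0.30, "hi": 0.70, "points": 41}
}
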