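{
  "name": "edelstein",
  "notes": "Edelstein reaction scheme: autocatalysis of x1 with an enzymatic sink through the conserved enzyme pool x2 + x3 = 30.",
  "variables": ["x1", "x2", "x3"],
  "parameters": {"k1": "8.5", "k2": "1", "k3": "1", "k4": "1", "k5": "1", "k6": "0.2", "c": "30"},
  "odes": {
    "x1": "k1*x1 - k2*x1^2 - k3*x1*x2 + k4*x3",
    "x2": "k4*x3 + k5*x3 - k3*x1*x2 - k6*x2"
  },
  "constraints": [
    {"coeffs": {"x2": "1", "x3": "1"}, "total": "30", "eliminate": "x3"}
  ],
  "order": ["x2", "x1"],
  "outputs": ["x1"]
}
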