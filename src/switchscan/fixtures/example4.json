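{
  "name": "example4",
  "notes": "Constructed three-species network with zeroth-order inflow v; the Y balance factors as Y*f3, so the steady-state variety splits into the Y=0 branch (one positive state) and the cofactor branch carrying the bistable triple. Table parameters 0.166 and 1.667 snap to 1/6 and 5/3.",
  "variables": ["Z", "X", "Y"],
  "parameters": {"k1": "1", "k2": "1", "k3": "0.166", "k4": "1", "k5": "0.166",
                 "k6": "1.667", "k7": "2", "k8": "16", "k9": "16", "v": "24"},
  "snap": {"0.166": "1/6", "1.667": "5/3"},
  "odes": {
    "Z": "v - k1*Z^2 - k4*Y*Z - k7*Z^3 - k8*Z + k9*Z^2",
    "X": "k1*Z^2 - k2*X",
    "Y": "-k3*X*Y + k4*Y*Z - k5*Y^2 + k6*Y"
  },
  "order": ["X", "Y", "Z"],
  "outputs": ["Z", "X", "Y"],
  "scan": {"parameter": "v", "lo": 20, "hi": 28, "points": 17}
}
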