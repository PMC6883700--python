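{
  "name": "example3",
  "notes": "Constructed bistable network whose output Y does not switch: Y is produced by two reactions whose reactant pool X + Z is conserved, so the total production rate (and hence Y) is the same at both stable states. Reduced Z/Y form after eliminating X = c - Z.",
  "variables": ["Z", "Y"],
  "parameters": {},
  "odes": {
    "Z": "-Z^3 + 6*Z^2 - 11*Z + 6",
    "Y": "-Y - Z^2 + 4*Z + 6"
  },
  "order": ["Z", "Y"],
  "outputs": ["Y", "Z"]
}
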