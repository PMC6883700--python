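{
  "name": "wilhelm",
  "notes": "Smallest mass-action reaction system with bistability: autocatalytic production of x fed by a lumped substrate S, with quadratic recycling to y, bilinear and linear degradation. S and P are boundary species; the constant [S] is folded into k1.",
  "variables": ["x", "y"],
  "boundary": ["S", "P"],
  "parameters": {"k1": "8", "k2": "1", "k3": "1", "k4": "1.5"},
  "reactions": [
    {"label": "S+Y->2X", "reactants": {"S": 1, "y": 1}, "products": {"x": 2}, "k": "k1"},
    {"label": "2X->X+Y", "reactants": {"x": 2}, "products": {"x": 1, "y": 1}, "k": "k2"},
    {"label": "X+Y->Y+P", "reactants": {"x": 1, "y": 1}, "products": {"y": 1, "P": 1}, "k": "k3"},
    {"label": "X->P", "reactants": {"x": 1}, "products": {"P": 1}, "k": "k4"}
  ],
  "order": ["y", "x"],
  "outputs": ["x", "y"]
}
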