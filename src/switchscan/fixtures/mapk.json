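{
  "name": "mapk",
  "notes": "Dual phosphorylation/dephosphorylation cycle of MEK with distributive kinetics: x, y, z are MEK, MEKpp, MEKp as fractions of total MEK (x + y + z = 1). Saturation constants Ksi and maximal rates Vmi are derived from the elementary constants; c and p are the RAF kinase and phosphatase concentrations (nM).",
  "variables": ["x", "y", "z"],
  "parameters": {"a1": "0.0204", "a2": "0.0493", "a3": "0.0564", "a4": "0.0326",
                 "d1": "10.386", "d2": "2.716", "d3": "10.088", "d4": "0.813",
                 "kk1": "7", "kk2": "11.13", "kk3": "3.57", "kk4": "1.13",
                 "MT": "5128", "c": "0.6", "p": "1"},
  "derived_parameters": {
    "Ks1": "(d1 + kk1)/(MT*a1)",
    "Ks2": "(d2 + kk2)/(MT*a2)",
    "Ks3": "(d3 + kk3)/(MT*a3)",
    "Ks4": "(d4 + kk4)/(MT*a4)",
    "Vm1": "kk1*c", "Vm2": "kk2*p", "Vm3": "kk3*c", "Vm4": "kk4*p"
  },
  "odes": {
    "x": "(Vm2*(z/Ks2))/(1 + y/Ks4 + z/Ks2) - (Vm1*(x/Ks1))/(1 + x/Ks1 + z/Ks3)",
    "y": "(Vm3*(z/Ks3))/(1 + x/Ks1 + z/Ks3) - (Vm4*(y/Ks4))/(1 + y/Ks4 + z/Ks2)"
  },
  "constraints": [
    {"coeffs": {"x": "1", "y": "1", "z": "1"}, "total": "1", "eliminate": "z"}
  ],
  "order": ["x", "y"],
  "outputs": ["y", "x", "z"]
}
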