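{
  "name": "ras",
  "notes": "Dimensionless RAS activation model: RT = RAS-GTP, RD = RAS-GDP (fractions of total RAS beta), S = free SOS complex, SRT/SRD its RAS-bound forms (fractions of total SOS alpha). Catalytic activation of RD by the SOS complexes is Michaelis-Menten, GAP-mediated deactivation likewise; two conservation laws eliminate RD and S.",
  "variables": ["RT", "SRT", "SRD", "RD", "S"],
  "parameters": {"beta": "200", "alpha": "10",
                 "k1": "1.125e-4", "k2": "1.0625e-4",
                 "km1": "3", "km2": "0.4",
                 "k3cat": "1.75", "k4cat": "0.003", "k5cat": "0.1",
                 "RGAP": "0.1",
                 "K3m": "2738.8", "K4m": "15230.4", "K5m": "17.869"},
  "odes": {
    "RT": "-beta*k2*S*RT + km2*SRT + k4cat*alpha*RD*SRD/(K4m + beta*RD) + k3cat*alpha*RD*SRT/(K3m + beta*RD) - k5cat*RGAP*RT/(K5m + beta*RT)",
    "SRT": "beta*k2*S*RT - km2*SRT",
    "SRD": "beta*k1*S*RD - km1*SRD"
  },
  "constraints": [
    {"coeffs": {"RD": "1", "RT": "1", "SRD": "0.05", "SRT": "0.05"}, "total": "1", "eliminate": "RD"},
    {"coeffs": {"S": "1", "SRD": "1", "SRT": "1"}, "total": "1", "eliminate": "S"}
  ],
  "order": ["SRT", "SRD", "RT"],
  "outputs": ["RT"]
}
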