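[
  {"id": "A", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 2], "sigma": [2, 2], "rho": 0.2},
   "control": {"mu": [0, 0], "sigma": [2, 2], "rho": 0.2}},
  {"id": "B", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 2], "sigma": [2, 2], "rho": 0.2},
   "control": {"mu": [0, 0], "sigma": [2, 2], "rho": 0.4}},
  {"id": "C", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 2], "sigma": [2, 2], "rho": 0.2},
   "control": {"mu": [0, 0], "sigma": [2, 2], "rho": -0.2}},
  {"id": "D", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 2], "sigma": [2, 2], "rho": 0.1},
   "control": {"mu": [0, 0], "sigma": [2, 2], "rho": 0.1}},
  {"id": "E", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 2], "sigma": [2, 2], "rho": -0.1},
   "control": {"mu": [0, 0], "sigma": [2, 2], "rho": -0.1}},
  {"id": "F", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 3], "sigma": [2, 2], "rho": 0.2},
   "control": {"mu": [0, 0], "sigma": [2, 2], "rho": 0.2}},
  {"id": "G", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 3], "sigma": [2, 2], "rho": 0.2},
   "control": {"mu": [0, 2], "sigma": [2, 2], "rho": 0.2}},
  {"id": "H", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 2], "sigma": [2, 3], "rho": 0.2},
   "control": {"mu": [0, 0], "sigma": [2, 3], "rho": 0.2}},
  {"id": "I", "approach": 2, "n": 100000, "prevalence": 0.2,
   "case":    {"mu": [1, 2], "sigma": [2, 1], "rho": 0.2},
   "control": {"mu": [0, 0], "sigma": [2, 1], "rho": 0.2}}
]
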