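[
  {"id": "A", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.2,  "adjusted_or": [1.5, 1.5]},
  {"id": "B", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": -0.1, "adjusted_or": [1.5, 1.5]},
  {"id": "C", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": -0.2, "adjusted_or": [1.5, 1.5]},
  {"id": "D", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.1,  "adjusted_or": [1.5, 1.5]},
  {"id": "E", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.4,  "adjusted_or": [1.5, 1.5]},
  {"id": "F", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.2,  "adjusted_or": [1.5, 1.2]},
  {"id": "G", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.2,  "adjusted_or": [1.2, 1.2]},
  {"id": "H", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.2,  "adjusted_or": [1.5, 3.0]},
  {"id": "I", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.2,  "adjusted_or": [0.8, 0.8]},
  {"id": "J", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": -0.1, "adjusted_or": [1.5, 0.8]},
  {"id": "K", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.2,  "adjusted_or": [1.5, 0.8]},
  {"id": "L", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 1], "rho": 0.4,  "adjusted_or": [1.5, 0.8]},
  {"id": "M", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 3], "rho": 0.2,  "adjusted_or": [1.5, 1.5]},
  {"id": "N", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 3], "rho": -0.2, "adjusted_or": [1.5, 1.5]},
  {"id": "O", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 3], "rho": 0.1,  "adjusted_or": [1.5, 1.5]},
  {"id": "P", "approach": 1, "n": 100000, "prevalence": 0.2, "mu": [0, 0], "sigma": [1, 3], "rho": 0.4,  "adjusted_or": [1.5, 1.5]}
]
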