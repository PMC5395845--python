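"""Develop a risk model in each of a few standard populations.

Simulates three whole-population (approach 1) scenarios that differ only
in predictor correlation, fits the two-predictor logistic model in each,
and prints the development AUC next to the SD of the linear predictor.
Higher correlation between same-direction predictors widens the linear
predictor's spread (more case-mix heterogeneity) and raises the AUC.
"""

import casemixsim as cm

specs = {s.id: s for s in cm.load_table1_specs()}
chosen = [specs[pid] for pid in ("C", "A", "E")]  # rho = -0.2, 0.2, 0.4

result = cm.develop_all(chosen, master_seed=1)
print("pop   rho    AUC    SD(LP)")
for pid in ("C", "A", "E"):
    r = result.reports[pid]
    print(f"{pid}    {specs[pid].rho:+.1f}  {r.auc:.3f}   {r.sd_lp:.2f}")
print("\nAUC rises with the correlation; the SD of the linear predictor "
      "tracks it exactly in rank.")
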