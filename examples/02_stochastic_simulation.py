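"""Full-mechanism Gillespie simulation versus the reduced models.

Simulates 300-replicate ensembles of the exact mass-action mechanism and
of the one-species sQ/tQ birth processes at excess enzyme (E_T = 20 K_M),
and reports how far each reduced ensemble mean strays from the full-model
fluctuation band.
"""

import numpy as np

import tqkin as tk

fx = tk.enzyme_fixture("test_enzyme")
mm = fx.params.mm()
cond = tk.make_condition(40.0, 0.2, fx.omega, mm=mm)  # E_T = 20 K_M

mean_full, sd_full, _ = tk.simulate_ensemble("full", fx.params, cond, 300, seed=1)
for kind in ("tQ", "sQ"):
    mean_red, sd_red, _ = tk.simulate_ensemble(kind, mm, cond, 300, seed=2)
    scale = np.maximum(np.maximum(sd_full, sd_red), 1e-9)
    z = np.max(np.abs(mean_red - mean_full) / scale)
    print(f"{kind} reduced model: max |mean deviation| = {z:5.2f} "
          f"fluctuation SDs (S_T*omega = {cond.substrate_counts} molecules)")

print()
print("The tQ birth process stays deep inside the full model's noise band")
print("even at 20-fold enzyme excess; the sQ process leaves it by many")
print("standard deviations because the Michaelis-Menten propensity is not")
print("valid when enzyme is abundant.")
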