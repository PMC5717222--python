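"""Sequential experiment design driven by posterior-scatter diagnosis.

Starts chymotrypsin at a scarce-enzyme, scarce-substrate assay
(E_T = S_T = 0.1 K_M), classifies the joint posterior scatter, and lets
the advisor request the next condition until both parameters are
identified.  The data provider is simulator-backed here; in the lab it
would be the instrument.
"""

import tqkin as tk

fx = tk.enzyme_fixture("chymotrypsin")   # truth: k_cat/K_M = 0.12 /s/M
priors = (tk.prior_from_mean(fx.params.k_cat), tk.prior_from_mean(fx.params.K_M))
seeds = iter(tk.child_seeds(7, 8, key=3).tolist())


def provider(cond):
    return tk.generate_datasets(fx.params, cond, 10, next(seeds))


result = tk.run_two_step_design(provider, fx.design_low, priors,
                                n_iterations=10_000, seed=7)
for step in result.trail:
    d = step["diagnosis"]
    print(f"step {step['step']}: E_T = {step['condition']['E_T']:6.2f} M, "
          f"label = {d['label']:10s} (log-corr {d['log_correlation']:5.2f}, "
          f"sd log K_M {d['km_log_sd']:5.2f}) -> "
          f"{step['recommendation']['action']}")

s = tk.summarize(result.draws)
kc = s["parameters"]["k_cat"]["mean"]
km = s["parameters"]["K_M"]["mean"]
print(f"\nfinal pooled estimates: k_cat = {kc:.3g} /s, K_M = {km:.3g} M, "
      f"efficiency = {kc / km:.3g} /s/M (truth {fx.params.efficiency:.3g})")
print("A correlated first-experiment scatter told the advisor to raise E_T")
print("100-fold; pooling the two experiments identified both parameters.")
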