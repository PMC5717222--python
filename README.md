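# tqkin — Bayesian progress-curve enzyme kinetics with the total-QSSA model

`tqkin` estimates the catalytic constant k_cat and the Michaelis constant
K_M of an enzyme from **product progress curves** — the full time series of
product accumulation in a single reaction — instead of classical
initial-velocity assays.  It is written for enzymologists and systems
biologists who need kinetic constants under conditions where the textbook
analysis breaks down: scarce substrate, abundant enzyme (in-vivo-like
regimes, nanobiosensors, drug-metabolizing enzymes), and strongly
stochastic, low-copy-number data.

## The model

The irreversible mechanism

```
E + S  <=>[k_f, k_b]  C  ->[k_cat]  E + P,      K_M = (k_b + k_cat)/k_f
```

admits two quasi-steady-state reductions of the product dynamics:

* **sQ model** (standard QSSA; the Michaelis–Menten equation)

  dP/dt = k_cat · E_T (S_T − P) / (K_M + S_T − P),

  valid only for scarce enzyme, E_T ≪ K_M + S_T;

* **tQ model** (total QSSA)

  dP/dt = k_cat · ( b − √(b² − 4 E_T (S_T − P)) ) / 2,  b = E_T + K_M + S_T − P,

  accurate across essentially all enzyme/substrate regimes.

Observed product counts P₀, P₁, … at times t₀, t₁, … enter a Markov
counting-process likelihood with per-interval intensity λᵢ equal to the
chosen rate law evaluated at P_{i−1} (in molecule counts):

L(k_cat, K_M) ∝ ∏ᵢ λᵢ^{nᵢ} e^{−λᵢ Δtᵢ},  nᵢ = Pᵢ − P_{i−1}.

With independent gamma priors, λᵢ = k_cat·gᵢ(K_M) makes the k_cat
conditional conjugate (sampled exactly); K_M is sampled by
Metropolis–Hastings on log K_M; joint estimation alternates the two
(MH-within-Gibbs).  Because a single experiment generally cannot identify
both parameters — the joint posterior is either a correlated ridge (only
k_cat/K_M identified) or a horizontal cloud (K_M drops out entirely) — the
package also ships a **design advisor** that classifies the posterior
scatter and prescribes the next assay condition; pooling the two
experiments identifies both parameters.

## Worked example

```python
import tqkin as tk

fx = tk.enzyme_fixture("test_enzyme")      # k_f=1/nM/s, k_b=k_cat=1/s, K_M=2 nM
mm = fx.params.mm()
prior_k, prior_km = tk.prior_from_mean(1.0), tk.prior_from_mean(2.0)

low  = tk.make_condition(0.2, 0.2, fx.omega, mm=mm)   # E_T = S_T = 0.1 K_M
high = tk.make_condition(40.0, 0.2, fx.omega, mm=mm)  # E_T = 20 K_M
curves = (tk.generate_datasets(fx.params, low, 20, seed=11)
          + tk.generate_datasets(fx.params, high, 20, seed=12))

draws = tk.sample_joint(curves, (prior_k, prior_km), 10_000, seed=3)
s = tk.summarize(draws)
print(s["parameters"]["k_cat"]["mean"], s["parameters"]["K_M"]["mean"])
```

prints

```
0.958  1.976
```

i.e. the pooled posterior recovers k_cat = 1 /s and K_M = 2 nM within ~4%
and ~1% from 40 intrinsically noisy stochastic curves (20 molecules of
substrate each in the scarce assay).  The scarce-enzyme curves pin the
ratio k_cat/K_M, the excess-enzyme curves pin k_cat alone; either set by
itself leaves one direction of parameter space unconstrained
(`tk.classify_scatter` reports which, and `tk.run_two_step_design`
automates the resulting acquire–infer–redesign loop — see `examples/`).

## Command line

```sh
tqkin simulate --fixture test_enzyme --et 0.2 --st 0.2 --n-curves 10 --seed 1 --out low.csv
tqkin infer --model tq --data low.csv --data high.csv --seed 3 \
      --prior-mean-kcat 1 --prior-mean-km 2 --out draws.csv
tqkin design --fixture chymotrypsin --n-curves 10 --seed 4 --out audit.json
```

Progress curves are plain CSV (`replicate,time,product`) with a JSON
sidecar `<file>.meta.json` holding `E_T`, `S_T`, `omega` (molecules per
concentration unit), seeds and provenance.  `infer` writes a draws CSV and
a `<out>.summary.json` with means, CVs, quantiles, log-scale correlation,
acceptance rate and the full resolved settings; `design` writes the audit
trail of every diagnosis and recommendation.

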