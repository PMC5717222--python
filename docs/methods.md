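# Methods

## Scope and model

`tqkin` treats the irreversible single-substrate mechanism
E + S ⇌ C → E + P with mass-action constants (k_f, k_b, k_cat), and works
throughout with the two classical quasi-steady-state reductions of the
product dynamics: the sQ (Michaelis–Menten) rate law and the tQ
(total-QSSA) rate law written in total substrate S_T − P.  The tQ law is
the package's workhorse because its validity does not require scarce
enzyme.  Reverse reaction (P → C), inhibition and multi-substrate
mechanisms are out of scope.

Both rate laws are homogeneous of degree 1 in (P, K_M, E_T, S_T), so the
same closed forms serve as concentration-space ODE right-hand sides and as
count-space stochastic propensities; the count scale is set by ω
(molecules per concentration unit).  The tQ law is evaluated in the
algebraically equivalent form 2·k_cat·E_T(S_T−P) / (b + √(b²−4E_T(S_T−P)))
because the textbook (b − √·)/2 form loses ~3 significant digits to
cancellation near full conversion.

### Validity indices

The sQ index E_T/(K_M+S_T) and the P-dependent tQ index
(K/2S_T)·(E_T+K_M+S_T)/√(b²−4E_T(S_T−P)) (K = k_b/k_f) are computed
pointwise and as a maximum over a 101-point P-grid.  They are advisory
sufficient conditions, never hard gates: the stochastic benchmarks show
the tQ model tracking the full mechanism even where its index is ~2.5.

### Limiting regimes, with their genuine boundaries

Two analytic limits guide the identifiability analysis and are enforced
as tests:

* **Equivalence** — for E_T ≤ 10⁻⁴(S_T+K_M) the two laws agree to better
  than 10⁻³ relative, uniformly in P, *provided* S_T ≲ 5 K_M: the
  relative gap tends to E_T/K_M as P → S_T, so no uniform 10⁻³ bound
  exists at extreme substrate excess.
* **K_M-insensitivity** — for K_M ≤ 10⁻²(E_T+S_T) doubling K_M moves the
  tQ rate by < 2% *in the enzyme-excess regime* (E_T ≳ 4 S_T).  Near the
  titration point E_T ≈ S_T − P the square root's branch point is
  genuinely K_M-sensitive (5–10% rate changes at E_T = S_T), which is
  also why progress curves observed deep into conversion at high S_T can
  carry real K_M information (see "Known limitations").

## Stochastic simulation

The full mechanism is simulated exactly (Gillespie SSA; channels: binding
at (k_f/ω)ES, unbinding at k_b·C, catalysis at k_cat·C) from E(0)=E_Tω,
S(0)=S_Tω, C(0)=P(0)=0; the reduced models as single-channel birth
processes with the rate-law propensity in counts.  Inner loops are numba
kernels; trajectories record every event when requested and always sample
the observation grid, padding the absorbing state after the last event.
Replicates draw distinct 31-bit seeds from a numpy `SeedSequence`
expansion of one master seed (de-duplicated deterministically), so
ensembles are bit-reproducible and independent.

Synthetic datasets are full-model trajectories sampled at the observation
grid; the only noise is intrinsic stochasticity.  The default observation
grid is 50 even points from 0 to the time the deterministic tQ curve
reaches 99% conversion (located by doubling + bisection on the ODE
solution).  ODE solutions use LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ (the tQ
law turns stiff near full conversion at high E_T), both configurable.

### Benchmark enzymes

* `test_enzyme`: k_f = 1 /nM/s, k_b = k_cat = 1 /s (K_M = 2 nM,
  K/K_M = 1/2), ω = 100 molecules/nM.  Only K_M ≈ 2 nM is dictated by the
  benchmark; the unit split is this package's choice.
* `chymotrypsin` / `urease` / `fumarase`: defined by catalytic
  efficiencies 0.12, 4·10⁵, 1.6·10⁸ s⁻¹M⁻¹ with K_M pinned at 1 M and
  k_b = k_cat (only the efficiency is published; any split preserves it);
  ω = 2000/M so the scarce assay holds 200 substrate molecules.
* Design conditions per enzyme: S_T = 0.1 K_M with E_T ∈ {0.1, 10} K_M.

The generator emulates intrinsic molecular noise at realistic low copy
numbers.  It does **not** emulate measurement noise, calibration drift,
enzyme inactivation or substrate depletion by side reactions, so passing
tests demonstrate correctness of the inference machinery under the model's
own assumptions, not robustness to instrument artifacts.

## Likelihood and samplers

Counts are modelled per interval as Poisson-like events with constant
intensity λᵢ = rate-law(P_{i−1}) in count units; the log-likelihood is
Σ nᵢ log λᵢ − λᵢΔtᵢ (parameter-free factors dropped; λᵢ=0 with nᵢ>0 gives
−∞; pooling over curves is additive; negative increments are data errors).
K_M supplied in concentration units is converted through each curve's ω.
Priors are gamma with shape m/v, rate 1/v (mean m, variance v·m; default
v = 10), placed on the concentration scale where benchmark parameter
values are O(1)–O(10⁸).

* **k_cat | K_M**: exact conjugate draw from
  Gamma(shape + Σnᵢ, rate + ΣgᵢΔtᵢ).  A generic random-walk MH sampler
  for the same conditional (with internal thinning; the target reduces to
  two sufficient statistics) is kept as a cross-validation route and is
  required to agree with the exact sampler to KS distance < 0.01.
* **K_M | k_cat**: MH on log K_M with a mixture proposal — 85%
  random-walk at an SD adapted during burn-in toward 20–40% acceptance
  (clamped to [10⁻³, 10], then frozen), 10% random-walk at 10× that SD,
  and 5% independence draws from the prior with exact Hastings
  correction.  The heavy-tailed and independence components exist because
  the K_M target is nearly flat below E_T + S_T; a plain random walk
  cannot traverse that stretch in practical chain lengths.
* **Joint**: Gibbs sweeps alternating the exact k_cat draw and one K_M MH
  step, plus a joint scale move shifting log k_cat and log K_M together.
  The scale move transports the chain along the k_cat/K_M ridge produced
  by single-condition data, where axis-aligned updates mix diffusively;
  on identified targets it is a cheap no-op.  Defaults: 10⁵ iterations,
  20% burn-in, no thinning, start at the prior means; all configurable,
  and every sampler is bit-reproducible from its seed.

## Design advisor

The joint posterior from one experimental condition is generically
unidentified in one of two ways: a **correlated** ridge (data pin only
k_cat/K_M; remedy: increase E_T or S_T) or a **horizontal** cloud (K_M
has dropped out because K_M ≪ E_T + S_T; remedy: decrease both).  The
classifier computes, on log-scale draws (hence invariant to unit
rescaling and draw reordering): the (log k_cat, log K_M) correlation ρ;
the absolute posterior SDs of both log-parameters; the spread ratio
versus the prior's log-SD; and the fraction of K_M draws below E_T + S_T.

Label rule (defaults in `ClassifierThresholds`): **identified** iff both
posterior log-SDs < 0.5 (each parameter known within ~×1.6); otherwise
**horizontal** iff |ρ| < 0.3, else **correlated**.  The identification
cutoff is absolute rather than prior-relative because the benchmark prior
rule (variance = 10 × mean) yields prior log-SDs between ~0.5 and ~10
depending on the parameter's numeric scale — against a prior log-SD of
10, a posterior still spanning two decades would look "contracted".
Measured identified posteriors in the benchmark studies have log-SDs
≤ 0.15 and unidentified ones ≥ 1, so the 0.5 cutoff sits in a wide
margin.  The spread ratio and the dashed-line fraction are still reported
in every diagnosis.  Recommendations map label → action deterministically
(correlated → ×100 on E_T by default, S_T by flag; horizontal → ÷100 on
both; identified → stop), and `run_two_step_design` iterates
acquire → pooled inference → classify up to `max_steps` (default 3),
building each next observation grid from the current posterior means —
the truth is unknown to the advisor.

Under the benchmark prior convention the urease and fumarase k_cat priors
(means 4·10⁵ and 1.6·10⁸ with variance 10× mean) have prior CVs of
10⁻²·⁵–10⁻⁴, so k_cat is effectively known a priori, K_M follows from one
scarce assay, and the loop honestly stops after a single experiment; for
the test enzyme and chymotrypsin the loop takes the canonical two steps
(correlated → identified).

## Study sizes used in validation

The validation suite runs scaled-down versions of the benchmark studies:
500-replicate ensembles for full-vs-reduced comparisons; 20 simulated
curves and 10⁴ MCMC iterations for recovery studies (the originating
study used 10² curves and 10⁵ iterations); design runs acquire 10 curves
per step, and design-recovery figures average 3 replicate runs with
derived seeds.  These sizes are the package's validation convention;
`scripts/acceptance.py` documents the exact recipe for the headline K_M
recovery.

## Known limitations

* **QSSA transient**: the full mechanism needs ~1/(k_f(E_T+S_T+K_M)) to
  build complex from C(0)=0, while both reduced models assume the
  quasi-steady complex from t = 0.  Reduced-model means therefore run
  ahead of the full-model mean by a small persistent offset — well inside
  the stochastic fluctuation band at benchmark copy numbers (≤ ~1σ at
  most conditions, ~3σ at the fastest one), but resolvable by ensemble
  means at high replicate counts, and the main source of the few-percent
  downward bias visible in tQ-based estimates.
* **Tail identifiability at high S_T**: with large molecule counts and
  grids reaching 99% conversion, the final bend of the progress curve
  (S_T − P ~ K_M) genuinely identifies K_M even from one curve, so
  "a single experiment never identifies both parameters" holds for the
  scarce-substrate designs the advisor works with, not universally.
* **Left-endpoint intensity**: λᵢ is evaluated at P_{i−1}; on 50-point
  grids this discretization contributes an O(1%) bias to rate-like
  parameters.  Denser grids reduce it.
* The MH samplers are single-chain; convergence diagnostics beyond
  acceptance-rate tracking (e.g. cross-chain statistics) are left to the
  user for unusual targets.
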