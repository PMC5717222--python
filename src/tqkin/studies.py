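"""Benchmark study drivers on the built-in enzyme fixtures.

These functions wire the simulator, the samplers and the design advisor
into the standard simulation studies the package is validated on: the
3 x 3 (E_T, S_T) condition grid around K_M, full-vs-reduced ensemble
agreement, single-parameter and pooled parameter recovery, and two-step
design efficiency recovery.  They are used by the test suite, the
acceptance script and the examples; all randomness flows from the single
``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .design import run_two_step_design
from .inference import (
    prior_from_mean,
    sample_joint,
    sample_kcat_conditional,
    sample_km_conditional,
    summarize,
)
from .models import ExperimentCondition, make_condition
from .simulate import (
    EnzymeFixture,
    child_seeds,
    enzyme_fixture,
    generate_datasets,
    simulate_ensemble,
)

__all__ = [
    "condition_grid",
    "ensemble_z",
    "grand_posterior_mean_kcat",
    "grand_posterior_mean_km",
    "pooled_joint_means",
    "design_efficiency_recovery",
]

#: the benchmark grid: each total below, at, and above K_M ~= 2 nM
GRID_E_T = (0.2, 2.0, 40.0)
GRID_S_T = (0.2, 2.0, 80.0)


def condition_grid(fx: EnzymeFixture | None = None,
                   n_points: int = 50) -> dict[tuple[float, float], ExperimentCondition]:
    """The 9 benchmark (E_T, S_T) conditions for the test enzyme (nM units)."""
    fx = fx or enzyme_fixture("test_enzyme")
    mm = fx.params.mm()
    return {(et, st): make_condition(et, st, fx.omega, mm=mm, n_points=n_points)
            for st in GRID_S_T for et in GRID_E_T}


def ensemble_z(params, cond: ExperimentCondition, kind: str, n_rep: int,
               seed: int, ref_kind: str = "full") -> np.ndarray:
    """Per-time z-scores between a reduced-model and a reference ensemble.

    z_j = (mean_kind - mean_ref) / sqrt(sd_kind^2/n + sd_ref^2/n); a point
    where both ensembles are deterministic (sd = 0) scores 0 when the
    means agree and +/- inf when they do not.  The two ensembles use
    disjoint seed substreams of ``seed``.
    """
    mm = params.mm()
    m_ref, s_ref, _ = simulate_ensemble(ref_kind, params, cond, n_rep, seed)
    m, s, _ = simulate_ensemble(kind, params if kind == "full" else mm,
                                cond, n_rep, seed + 1)
    se = np.sqrt((s**2 + s_ref**2) / n_rep)
    diff = m - m_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / se
    z[(se == 0) & (diff == 0)] = 0.0
    z[(se == 0) & (diff != 0)] = np.inf * np.sign(diff[(se == 0) & (diff != 0)])
    return z


def _per_curve_seeds(seed: int, n: int, key: int) -> np.ndarray:
    return child_seeds(seed, n, key=key)


def grand_posterior_mean_kcat(params, cond: ExperimentCondition, model: str,
                              n_curves: int, n_draws: int, seed: int,
                              variance_multiplier: float = 10.0) -> float:
    """Average per-curve posterior-mean k_cat, K_M fixed at its true value.

    The benchmark convention: priors centred on the truth with variance
    10x the mean; one conjugate-gamma posterior per simulated curve; the
    per-curve posterior means are averaged.
    """
    curves = generate_datasets(params, cond, n_curves, seed)
    prior = prior_from_mean(params.k_cat, variance_multiplier)
    seeds = _per_curve_seeds(seed, n_curves, key=11)
    means = [sample_kcat_conditional(params.K_M, [c], prior, n_draws,
                                     int(seeds[i]), model=model).k_cat.mean()
             for i, c in enumerate(curves)]
    return float(np.mean(means))


def grand_posterior_mean_km(params, cond: ExperimentCondition, model: str,
                            n_curves: int, n_iterations: int, seed: int,
                            variance_multiplier: float = 10.0) -> float:
    """Average per-curve posterior-mean K_M, k_cat fixed at its true value."""
    curves = generate_datasets(params, cond, n_curves, seed)
    prior = prior_from_mean(params.K_M, variance_multiplier)
    seeds = _per_curve_seeds(seed, n_curves, key=12)
    means = [sample_km_conditional(params.k_cat, [c], prior, n_iterations,
                                   int(seeds[i]), model=model).K_M.mean()
             for i, c in enumerate(curves)]
    return float(np.mean(means))


def pooled_joint_means(params, conds, model: str, n_curves_each: int,
                       n_iterations: int, seed: int,
                       variance_multiplier: float = 10.0) -> dict:
    """Joint posterior means from curves pooled across conditions."""
    curves = []
    seeds = _per_curve_seeds(seed, len(conds), key=13)
    for i, cond in enumerate(conds):
        curves.extend(generate_datasets(params, cond, n_curves_each,
                                        int(seeds[i])))
    priors = (prior_from_mean(params.k_cat, variance_multiplier),
              prior_from_mean(params.K_M, variance_multiplier))
    draws = sample_joint(curves, priors, n_iterations, seed, model=model)
    summ = summarize(draws)
    return {"k_cat": summ["parameters"]["k_cat"]["mean"],
            "K_M": summ["parameters"]["K_M"]["mean"],
            "draws": draws}


def design_efficiency_recovery(name: str, seed: int,
                               n_iterations: int = 10_000,
                               n_curves: int = 1) -> dict:
    """Two-step design on a named enzyme; returns estimated vs true values.

    Starts at the fixture's low design condition (E_T = S_T = 0.1 K_M),
    lets the advisor request further experiments, and reports the pooled
    posterior-mean k_cat, K_M and catalytic efficiency.
    """
    fx = enzyme_fixture(name)
    priors = (prior_from_mean(fx.params.k_cat), prior_from_mean(fx.params.K_M))
    acq = iter(child_seeds(seed, 16, key=3).tolist())

    def provider(cond):
        return generate_datasets(fx.params, cond, n_curves, next(acq))

    res = run_two_step_design(provider, fx.design_low, priors,
                              n_iterations=n_iterations, seed=seed)
    summ = summarize(res.draws)
    kc = summ["parameters"]["k_cat"]["mean"]
    km = summ["parameters"]["K_M"]["mean"]
    return {"k_cat": kc, "K_M": km, "efficiency": kc / km,
            "true_k_cat": fx.params.k_cat, "true_K_M": fx.params.K_M,
            "true_efficiency": fx.params.efficiency,
            "steps": [t["diagnosis"]["label"] for t in res.trail],
            "trail": res.trail}
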