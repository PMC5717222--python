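"""Deterministic rate laws for the Michaelis-Menten reaction scheme.

The irreversible mechanism E + S <-> C -> E + P admits two classical
quasi-steady-state reductions for the product progress curve P(t):

* the **sQ model** (standard QSSA, the Michaelis-Menten equation)

      dP/dt = k_cat * E_T * (S_T - P) / (K_M + S_T - P),

  accurate only when enzyme is scarce, E_T << K_M + S_T;

* the **tQ model** (total QSSA)

      dP/dt = k_cat * (b - sqrt(b^2 - 4 E_T (S_T - P))) / 2,
      b = E_T + K_M + S_T - P,

  accurate over essentially all enzyme/substrate regimes.

This module provides both rate laws, their (advisory) validity indices,
and ODE progress-curve solutions on an observation grid.  All quantities
are unit-agnostic but must be mutually consistent (e.g. nM and s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "MMParams",
    "ExperimentCondition",
    "sq_rate",
    "tq_rate",
    "sq_validity_index",
    "tq_validity_index",
    "tq_validity_index_max",
    "solve_deterministic",
    "solve_mass_action",
    "conversion_time",
    "default_time_grid",
    "make_condition",
]


@dataclass(frozen=True)
class KineticParams:
    """Microscopic mass-action rate constants of the full mechanism.

    Parameters
    ----------
    k_f : float
        Bimolecular association rate constant (concentration^-1 time^-1).
    k_b : float
        Complex dissociation rate constant (time^-1).
    k_cat : float
        Catalytic rate constant (time^-1).
    """

    k_f: float
    k_b: float
    k_cat: float

    def __post_init__(self) -> None:
        for name in ("k_f", "k_b", "k_cat"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def K_M(self) -> float:
        """Michaelis-Menten constant (k_b + k_cat) / k_f."""
        return (self.k_b + self.k_cat) / self.k_f

    @property
    def K(self) -> float:
        """Dissociation constant k_b / k_f (0 < K <= K_M)."""
        return self.k_b / self.k_f

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency k_cat / K_M."""
        return self.k_cat / self.K_M

    def mm(self) -> "MMParams":
        """The (k_cat, K_M) pair the reduced models depend on."""
        return MMParams(k_cat=self.k_cat, K_M=self.K_M)


@dataclass(frozen=True)
class MMParams:
    """The inference-level parameter pair (k_cat, K_M)."""

    k_cat: float
    K_M: float

    def __post_init__(self) -> None:
        if not self.k_cat > 0:
            raise ValueError("k_cat must be strictly positive")
        if not self.K_M > 0:
            raise ValueError("K_M must be strictly positive")


@dataclass(frozen=True)
class ExperimentCondition:
    """One assay condition: totals, count scaling and observation grid.

    Parameters
    ----------
    E_T, S_T : float
        Total enzyme / substrate concentration (>= 0).
    omega : float
        Count-scaling factor: molecules per concentration unit (> 0).
    t_obs : ndarray
        Strictly increasing observation times starting at 0.
    """

    E_T: float
    S_T: float
    omega: float
    t_obs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.E_T < 0 or self.S_T < 0:
            raise ValueError("E_T and S_T must be nonnegative")
        if not self.omega > 0:
            raise ValueError("omega must be strictly positive")
        t = np.asarray(self.t_obs, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("t_obs must be a 1-D grid with at least 2 points")
        if t[0] != 0.0:
            raise ValueError("t_obs must start at 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t_obs must be strictly increasing")
        object.__setattr__(self, "t_obs", t)

    @property
    def substrate_counts(self) -> int:
        """Initial substrate molecule count round(S_T * omega)."""
        return int(round(self.S_T * self.omega))

    @property
    def enzyme_counts(self) -> int:
        """Initial enzyme molecule count round(E_T * omega)."""
        return int(round(self.E_T * self.omega))

    def with_totals(self, E_T: float | None = None, S_T: float | None = None,
                    t_obs: np.ndarray | None = None) -> "ExperimentCondition":
        return ExperimentCondition(
            E_T=self.E_T if E_T is None else E_T,
            S_T=self.S_T if S_T is None else S_T,
            omega=self.omega,
            t_obs=self.t_obs if t_obs is None else t_obs,
        )


# -- rate-law cores ---------------------------------------------------------
# Array-friendly and unit-agnostic: used on the concentration scale by the
# public wrappers below and on the count scale by the likelihood and the
# reduced-model propensities (both laws are homogeneous of degree 1).

def sq_rate_core(P, k_cat, K_M, E_T, S_T):
    P = np.asarray(P, dtype=float)
    denom = K_M + S_T - P
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = k_cat * E_T * (S_T - P) / denom
    # denom can hit 0 only when P = S_T and K_M underflows: rate is 0 there
    return np.where(denom > 0.0, rate, 0.0)


def tq_rate_core(P, k_cat, K_M, E_T, S_T):
    P = np.asarray(P, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        b = E_T + K_M + S_T - P
        c = 4.0 * E_T * (S_T - P)
        # exact arithmetic gives disc >= 0; guard against float cancellation
        disc = np.maximum(b * b - c, 0.0)
        # (b - sqrt(disc))/2 rewritten as c / (2 (b + sqrt(disc))): the
        # direct form cancels catastrophically near full conversion
        # (b ~ sqrt(disc)); b*b may overflow for extreme K_M proposals,
        # where the rate correctly underflows to 0
        denom = b + np.sqrt(disc)
        rate = k_cat * c / (2.0 * denom)
    return np.where(denom > 0.0, rate, 0.0)


def _check_P(P, S_T):
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > S_T):
        raise ValueError(f"product P must lie in [0, S_T={S_T}]")
    return P


def sq_rate(P, mm: MMParams, cond: ExperimentCondition):
    """Michaelis-Menten (sQ) production rate dP/dt at product level P."""
    P = _check_P(P, cond.S_T)
    return sq_rate_core(P, mm.k_cat, mm.K_M, cond.E_T, cond.S_T)


def tq_rate(P, mm: MMParams, cond: ExperimentCondition):
    """Total-QSSA (tQ) production rate dP/dt at product level P."""
    P = _check_P(P, cond.S_T)
    return tq_rate_core(P, mm.k_cat, mm.K_M, cond.E_T, cond.S_T)


def sq_validity_index(mm: MMParams, cond: ExperimentCondition) -> float:
    """E_T / (K_M + S_T): the sQ model is trusted when this is << 1.

    A sufficient condition only; the index is advisory, never a hard gate.
    """
    denom = mm.K_M + cond.S_T
    if not denom > 0:
        raise ValueError("K_M + S_T must be positive")
    return cond.E_T / denom


def tq_validity_index(params: KineticParams, cond: ExperimentCondition, P):
    """Pointwise tQ validity index; the tQ model is trusted when << 1.

    (K / 2 S_T) * (E_T + K_M + S_T) / sqrt((E_T + K_M + S_T - P)^2
    - 4 E_T (S_T - P)).  Depends on the product level P; see
    :func:`tq_validity_index_max` for the trajectory-wide summary.
    """
    if not cond.S_T > 0:
        raise ValueError("S_T must be positive for the tQ validity index")
    P = _check_P(P, cond.S_T)
    K_M = params.K_M
    b = cond.E_T + K_M + cond.S_T - P
    disc = np.maximum(b * b - 4.0 * cond.E_T * (cond.S_T - P), 0.0)
    return (params.K / (2.0 * cond.S_T)) * (cond.E_T + K_M + cond.S_T) / np.sqrt(disc)


def tq_validity_index_max(params: KineticParams, cond: ExperimentCondition,
                          n_grid: int = 101) -> float:
    """Maximum of the pointwise tQ index over an even P-grid on [0, S_T]."""
    grid = np.linspace(0.0, cond.S_T, n_grid)
    return float(np.max(tq_validity_index(params, cond, grid)))


_RATE_CORES = {"sQ": sq_rate_core, "tQ": tq_rate_core}


def _normalize_model(model: str) -> str:
    key = {"sq": "sQ", "tq": "tQ"}.get(str(model).lower())
    if key is None:
        raise ValueError(f"unknown model {model!r}; expected 'sQ' or 'tQ'")
    return key


def solve_deterministic(model: str, mm: MMParams, cond: ExperimentCondition,
                        rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Integrate the chosen rate law; return P on ``cond.t_obs``.

    Uses a stiff-capable adaptive integrator (LSODA): the tQ law becomes
    stiff near full conversion at high E_T.  The solution is checked to be
    nondecreasing and bounded by S_T (to solver tolerance) and then clipped
    onto [0, S_T].
    """
    model = _normalize_model(model)
    core = _RATE_CORES[model]
    k_cat, K_M, E_T, S_T = mm.k_cat, mm.K_M, cond.E_T, cond.S_T

    def rhs(t, y):
        P = min(max(y[0], 0.0), S_T)
        return [float(core(P, k_cat, K_M, E_T, S_T))]

    sol = solve_ivp(rhs, (cond.t_obs[0], cond.t_obs[-1]), [0.0],
                    t_eval=cond.t_obs, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed for the {model} model: "
                           f"{sol.message} (E_T={E_T}, S_T={S_T})")
    P = sol.y[0]
    slack = 1e-6 * max(S_T, 1.0)
    if np.any(P > S_T + slack) or np.any(np.diff(P) < -slack):
        raise RuntimeError(f"{model} solution violates monotone depletion; "
                           "tighten rtol/atol")
    return np.clip(np.maximum.accumulate(P), 0.0, S_T)


def solve_mass_action(params: KineticParams, cond: ExperimentCondition,
                      rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Product curve of the full mass-action mechanism (no QSSA) on t_obs.

    Integrates dS/dt = -k_f (E_T - C) S + k_b C and
    dC/dt = k_f (E_T - C) S - (k_b + k_cat) C from S(0) = S_T, C(0) = 0;
    P = S_T - S - C.  This is the thermodynamic (large-count) limit of the
    stochastic mechanism and the reference the reduced models approximate.
    """
    k_f, k_b, k_cat = params.k_f, params.k_b, params.k_cat
    E_T, S_T = cond.E_T, cond.S_T

    def rhs(t, y):
        S, C = y
        bind = k_f * (E_T - C) * S
        return [-bind + k_b * C, bind - (k_b + k_cat) * C]

    sol = solve_ivp(rhs, (cond.t_obs[0], cond.t_obs[-1]), [S_T, 0.0],
                    t_eval=cond.t_obs, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"mass-action integration failed: {sol.message}")
    P = S_T - sol.y[0] - sol.y[1]
    return np.clip(np.maximum.accumulate(P), 0.0, S_T)


def conversion_time(mm: MMParams, cond_like, fraction: float = 0.99,
                    model: str = "tQ", rel_tol: float = 1e-3) -> float:
    """Time at which the deterministic solution reaches ``fraction * S_T``.

    Located by doubling then bisection on the ODE solution.  ``cond_like``
    needs only E_T, S_T (omega/t_obs are ignored).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    E_T, S_T = cond_like.E_T, cond_like.S_T
    if E_T <= 0 or S_T <= 0:
        raise ValueError("conversion_time needs E_T > 0 and S_T > 0")
    target = fraction * S_T
    core = _RATE_CORES[_normalize_model(model)]

    def P_at(t: float) -> float:
        def rhs(_, y):
            P = min(max(y[0], 0.0), S_T)
            return [float(core(P, mm.k_cat, mm.K_M, E_T, S_T))]
        sol = solve_ivp(rhs, (0.0, t), [0.0], method="LSODA",
                        rtol=1e-8, atol=1e-10 * max(S_T, 1.0))
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return float(sol.y[0][-1])

    # initial scale from the harmonic mean of the two limiting rates
    r0 = float(core(0.0, mm.k_cat, mm.K_M, E_T, S_T))
    if r0 <= 0:
        raise RuntimeError("initial rate is zero; no conversion occurs")
    hi = S_T / r0
    while P_at(hi) < target:
        hi *= 2.0
        if hi > 1e12 * S_T / r0:
            raise RuntimeError("conversion time search did not converge")
    lo = 0.0
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if P_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def default_time_grid(mm: MMParams, cond_like, n_points: int = 50,
                      fraction: float = 0.99) -> np.ndarray:
    """Evenly spaced observation grid from 0 to the 99%-conversion time."""
    t_end = conversion_time(mm, cond_like, fraction=fraction)
    return np.linspace(0.0, t_end, n_points)


def make_condition(E_T: float, S_T: float, omega: float,
                   mm: MMParams | None = None,
                   t_obs: np.ndarray | None = None,
                   n_points: int = 50) -> ExperimentCondition:
    """Build an :class:`ExperimentCondition`, defaulting the observation grid.

    If ``t_obs`` is omitted, ``mm`` must be given and the grid is 50 even
    points from 0 to the deterministic tQ 99%-conversion time.
    """
    if t_obs is None:
        if mm is None:
            raise ValueError("either t_obs or mm (for the default grid) is required")
        from types import SimpleNamespace
        t_obs = default_time_grid(mm, SimpleNamespace(E_T=E_T, S_T=S_T),
                                  n_points=n_points)
    return ExperimentCondition(E_T=E_T, S_T=S_T, omega=omega, t_obs=t_obs)
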