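"""Exact stochastic simulation of the enzyme mechanism and its reductions.

The full mechanism is simulated with the Gillespie algorithm over three
channels (counts E, S, C, P; binding propensity (k_f/omega)*E*S, unbinding
k_b*C, catalysis k_cat*C).  The reduced sQ/tQ models are simulated as pure
birth processes with a single channel P -> P+1 whose propensity is the
corresponding rate law evaluated in count units (both laws are homogeneous
of degree 1, so the count-space propensity equals omega times the
concentration-space rate).

Replicates draw their seeds from per-replicate substreams of one master
``numpy.random.SeedSequence``, so an ensemble is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .models import (
    ExperimentCondition,
    KineticParams,
    MMParams,
    make_condition,
)

__all__ = [
    "Trajectory",
    "ProgressCurve",
    "gillespie_full",
    "gillespie_reduced",
    "simulate_ensemble",
    "generate_datasets",
    "enzyme_fixture",
    "EnzymeFixture",
    "child_seeds",
]

_MODEL_FLAG = {"sQ": 0, "tQ": 1}


def child_seeds(master_seed: int, n: int, key: int = 0) -> np.ndarray:
    """``n`` distinct 31-bit seeds from one master seed.

    ``key`` separates logical streams (e.g. different ensembles) driven by
    the same master seed.  Seeds are drawn from the counter-based
    SeedSequence expansion and de-duplicated deterministically, so
    replicates never share a stream (31-bit birthday collisions would
    otherwise occur once in ~1e4 ensembles of 500).
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(key),))
    k = max(n, 2)
    while True:
        vals = (ss.generate_state(k, dtype=np.uint64) % np.uint64(2**31)).astype(np.int64)
        _, idx = np.unique(vals, return_index=True)
        if idx.size >= n:
            return vals[np.sort(idx)[:n]]
        k *= 2


@dataclass
class Trajectory:
    """One stochastic realization: event history plus sampled observations.

    ``E``, ``S``, ``C`` are ``None`` for reduced-model trajectories, which
    track only the product count.
    """

    condition: ExperimentCondition
    times: np.ndarray
    P: np.ndarray
    E: np.ndarray | None = None
    S: np.ndarray | None = None
    C: np.ndarray | None = None
    P_obs: np.ndarray = field(default=None)
    provenance: str = "full"
    seed: int = 0

    def progress_curve(self) -> "ProgressCurve":
        return ProgressCurve(condition=self.condition,
                             P_obs=np.asarray(self.P_obs, dtype=np.int64),
                             provenance=self.provenance, seed=self.seed)


@dataclass
class ProgressCurve:
    """Observed product counts at the condition's observation times."""

    condition: ExperimentCondition
    P_obs: np.ndarray
    provenance: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.P_obs, dtype=np.int64)
        if P.shape != self.condition.t_obs.shape:
            raise ValueError("P_obs and t_obs must have the same length")
        if P[0] != 0:
            raise ValueError("P_obs must start at 0")
        if np.any(np.diff(P) < 0):
            raise ValueError("P_obs must be nondecreasing")
        if np.any(P > self.condition.substrate_counts):
            raise ValueError("P_obs exceeds the total substrate count")
        self.P_obs = P


# -- numba kernels ----------------------------------------------------------

@njit(cache=True)
def _ssa_full_kernel(seed, e0, s0, kf_c, kb, kcat, t_obs,
                     ev_t, ev_E, ev_S, ev_C, ev_P, record):
    """Exact SSA of the full mechanism.

    Returns (P at t_obs, number of recorded events incl. initial state,
    overflow flag).  With ``record`` the state after every event is written
    into the ev_* buffers (index 0 holds the initial state).
    """
    np.random.seed(seed)
    E = e0
    S = s0
    C = 0
    P = 0
    t = 0.0
    n_obs = t_obs.shape[0]
    P_out = np.empty(n_obs, dtype=np.int64)
    obs_i = 0
    n_ev = 0
    overflow = False
    if record:
        ev_t[0] = 0.0
        ev_E[0] = E
        ev_S[0] = S
        ev_C[0] = C
        ev_P[0] = P
        n_ev = 1
    t_end = t_obs[n_obs - 1]
    while True:
        a1 = kf_c * E * S
        a2 = kb * C
        a3 = kcat * C
        a0 = a1 + a2 + a3
        if a0 <= 0.0:
            break
        t_next = t - np.log(np.random.random()) / a0
        while obs_i < n_obs and t_obs[obs_i] < t_next:
            P_out[obs_i] = P
            obs_i += 1
        if t_next > t_end:
            t = t_next
            break
        u = np.random.random() * a0
        if u < a1:
            E -= 1
            S -= 1
            C += 1
        elif u < a1 + a2:
            E += 1
            S += 1
            C -= 1
        else:
            E += 1
            C -= 1
            P += 1
        t = t_next
        if record:
            if n_ev < ev_t.shape[0]:
                ev_t[n_ev] = t
                ev_E[n_ev] = E
                ev_S[n_ev] = S
                ev_C[n_ev] = C
                ev_P[n_ev] = P
            else:
                overflow = True
            n_ev += 1
    while obs_i < n_obs:  # absorbing pad
        P_out[obs_i] = P
        obs_i += 1
    return P_out, n_ev, overflow


@njit(cache=True)
def _ssa_reduced_kernel(seed, model_flag, s0, kcat, km_c, et_c, st_c, t_obs,
                        ev_t, record):
    """Pure-birth SSA for a reduced model; propensity in count units.

    ev_t receives the jump time of the k-th product molecule; at most s0
    events occur, so the buffer never overflows when sized s0.
    """
    np.random.seed(seed)
    P = 0
    t = 0.0
    n_obs = t_obs.shape[0]
    P_out = np.empty(n_obs, dtype=np.int64)
    obs_i = 0
    t_end = t_obs[n_obs - 1]
    while True:
        rem = st_c - P
        if model_flag == 0:
            lam = kcat * et_c * rem / (km_c + rem)
        else:
            b = et_c + km_c + rem
            c = 4.0 * et_c * rem
            disc = b * b - c
            if disc < 0.0:
                disc = 0.0
            lam = kcat * c / (2.0 * (b + np.sqrt(disc)))  # stable tQ form
        if lam <= 0.0 or P >= s0:
            break
        t_next = t - np.log(np.random.random()) / lam
        while obs_i < n_obs and t_obs[obs_i] < t_next:
            P_out[obs_i] = P
            obs_i += 1
        if t_next > t_end:
            t = t_next
            break
        P += 1
        t = t_next
        if record:
            ev_t[P - 1] = t
    while obs_i < n_obs:
        P_out[obs_i] = P
        obs_i += 1
    return P_out, P


# -- public simulators ------------------------------------------------------

def _integer_counts(cond: ExperimentCondition) -> tuple[int, int]:
    e_exact = cond.E_T * cond.omega
    s_exact = cond.S_T * cond.omega
    e0, s0 = round(e_exact), round(s_exact)
    tol = 1e-6
    if abs(e_exact - e0) > tol * max(1.0, e_exact) or \
       abs(s_exact - s0) > tol * max(1.0, s_exact):
        raise ValueError(
            f"omega={cond.omega} does not give integer initial counts "
            f"(E_T*omega={e_exact}, S_T*omega={s_exact})")
    return int(e0), int(s0)


def gillespie_full(params: KineticParams, cond: ExperimentCondition,
                   seed: int, record_events: bool = True) -> Trajectory:
    """One exact SSA trajectory of the full mass-action mechanism."""
    e0, s0 = _integer_counts(cond)
    kf_c = params.k_f / cond.omega
    cap = 16 + 8 * (s0 + e0)
    while True:
        ev_t = np.empty(cap if record_events else 1, dtype=np.float64)
        ev = [np.empty(cap if record_events else 1, dtype=np.int64)
              for _ in range(4)]
        P_obs, n_ev, overflow = _ssa_full_kernel(
            np.int64(seed), e0, s0, kf_c, params.k_b, params.k_cat,
            cond.t_obs, ev_t, ev[0], ev[1], ev[2], ev[3], record_events)
        if not (record_events and overflow):
            break
        cap = 2 * n_ev  # rerun with a larger buffer; same seed, same path
    if record_events:
        return Trajectory(condition=cond, times=ev_t[:n_ev].copy(),
                          E=ev[0][:n_ev].copy(), S=ev[1][:n_ev].copy(),
                          C=ev[2][:n_ev].copy(), P=ev[3][:n_ev].copy(),
                          P_obs=P_obs, provenance="full", seed=int(seed))
    return Trajectory(condition=cond, times=np.empty(0), P=np.empty(0, np.int64),
                      P_obs=P_obs, provenance="full", seed=int(seed))


def gillespie_reduced(model: str, mm: MMParams, cond: ExperimentCondition,
                      seed: int, record_events: bool = True) -> Trajectory:
    """One SSA trajectory of a reduced (single-channel) model."""
    model = "sQ" if str(model).lower() == "sq" else "tQ" if str(model).lower() == "tq" else model
    if model not in _MODEL_FLAG:
        raise ValueError(f"unknown model {model!r}; expected 'sQ' or 'tQ'")
    _, s0 = _integer_counts(cond)
    om = cond.omega
    ev_t = np.empty(max(s0, 1) if record_events else 1, dtype=np.float64)
    P_obs, n_ev = _ssa_reduced_kernel(
        np.int64(seed), _MODEL_FLAG[model], s0, mm.k_cat,
        mm.K_M * om, cond.E_T * om, cond.S_T * om, cond.t_obs,
        ev_t, record_events)
    if record_events:
        times = np.concatenate(([0.0], ev_t[:n_ev]))
        P = np.arange(n_ev + 1, dtype=np.int64)
    else:
        times, P = np.empty(0), np.empty(0, np.int64)
    return Trajectory(condition=cond, times=times, P=P, P_obs=P_obs,
                      provenance=model, seed=int(seed))


def _simulate_P_obs(kind: str, params, cond: ExperimentCondition,
                    seed: int) -> np.ndarray:
    if kind == "full":
        return gillespie_full(params, cond, seed, record_events=False).P_obs
    return gillespie_reduced(kind, params, cond, seed, record_events=False).P_obs


def simulate_ensemble(kind: str, params, cond: ExperimentCondition,
                      n_rep: int, seed: int):
    """Ensemble mean and sample-SD curves over independent replicates.

    Parameters
    ----------
    kind : {"full", "sQ", "tQ"}
        Which simulator to run; ``params`` is a :class:`KineticParams` for
        "full" and an :class:`MMParams` for the reduced models.
    n_rep : int
        Number of replicates (>= 2).
    seed : int
        Master seed; replicate seeds are derived substreams.

    Returns
    -------
    mean, sd, P : ndarray
        Per-time-point mean and sample SD (ddof=1), and the (n_rep, n_obs)
        matrix of sampled product counts.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2 for an ensemble")
    if kind == "full" and isinstance(params, KineticParams):
        pass
    elif kind in ("sQ", "tQ") and isinstance(params, MMParams):
        pass
    else:
        raise ValueError(f"kind {kind!r} incompatible with params type "
                         f"{type(params).__name__}")
    seeds = child_seeds(seed, n_rep)
    if len(set(seeds.tolist())) != n_rep:  # pragma: no cover - astronomically rare
        raise RuntimeError("replicate seeds collide; replicates must be independent")
    P = np.empty((n_rep, cond.t_obs.size), dtype=np.int64)
    for r in range(n_rep):
        P[r] = _simulate_P_obs(kind, params, cond, int(seeds[r]))
    return P.mean(axis=0), P.std(axis=0, ddof=1), P


def generate_datasets(params: KineticParams, cond: ExperimentCondition,
                      n_datasets: int, seed: int) -> list[ProgressCurve]:
    """Noisy progress curves: full-model SSA sampled at ``cond.t_obs``.

    The only noise is intrinsic Gillespie stochasticity; no measurement
    noise is added.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    seeds = child_seeds(seed, n_datasets, key=1)
    curves = []
    for r in range(n_datasets):
        traj = gillespie_full(params, cond, int(seeds[r]), record_events=False)
        curves.append(traj.progress_curve())
    return curves


# -- enzyme fixtures --------------------------------------------------------

@dataclass(frozen=True)
class EnzymeFixture:
    """A named enzyme with ground-truth constants and design conditions.

    ``design_low`` / ``design_high`` are the recommended first/second assay
    conditions: S_T = 0.1 K_M with E_T = 0.1 K_M and 10 K_M respectively.
    """

    name: str
    params: KineticParams
    omega: float
    conc_unit: str
    design_low: ExperimentCondition
    design_high: ExperimentCondition


def _efficiency_fixture(name: str, efficiency: float) -> EnzymeFixture:
    # K_M pinned at 1 M and k_b = k_cat: only the efficiency is published,
    # and any split preserves k_cat / K_M.
    K_M = 1.0
    k_cat = efficiency * K_M
    params = KineticParams(k_f=2.0 * k_cat / K_M, k_b=k_cat, k_cat=k_cat)
    S_T = 0.1 * K_M
    omega = 200.0 / S_T  # ~200 substrate molecules in the low-S_T assay
    mm = params.mm()
    low = make_condition(0.1 * K_M, S_T, omega, mm=mm)
    high = make_condition(10.0 * K_M, S_T, omega, mm=mm)
    return EnzymeFixture(name=name, params=params, omega=omega, conc_unit="M",
                         design_low=low, design_high=high)


def enzyme_fixture(name: str) -> EnzymeFixture:
    """Built-in enzymes for simulation studies.

    * ``test_enzyme`` — k_f = 1 /nM/s, k_b = k_cat = 1 /s, so K_M = 2 nM;
      omega = 100 molecules/nM.
    * ``chymotrypsin`` / ``urease`` / ``fumarase`` — catalytic efficiencies
      0.12, 4e5 and 1.6e8 /s/M with K_M pinned at 1 M (units: M, s).
    """
    name = name.lower()
    if name == "test_enzyme":
        params = KineticParams(k_f=1.0, k_b=1.0, k_cat=1.0)  # nM, s units
        omega = 100.0
        K_M = params.K_M
        mm = params.mm()
        low = make_condition(0.1 * K_M, 0.1 * K_M, omega, mm=mm)
        high = make_condition(10.0 * K_M, 0.1 * K_M, omega, mm=mm)
        return EnzymeFixture(name="test_enzyme", params=params, omega=omega,
                             conc_unit="nM", design_low=low, design_high=high)
    efficiencies = {"chymotrypsin": 0.12, "urease": 4e5, "fumarase": 1.6e8}
    if name in efficiencies:
        return _efficiency_fixture(name, efficiencies[name])
    raise ValueError(
        f"unknown enzyme fixture {name!r}; available: "
        "test_enzyme, chymotrypsin, urease, fumarase")
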