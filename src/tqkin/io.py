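"""File formats: progress-curve CSV + JSON sidecar, draws CSV, summaries.

Progress curves travel as comma-separated text with a mandatory header
(columns ``replicate``, ``time``, ``product``; "." decimal) and a metadata
sidecar ``<data>.meta.json`` carrying E_T, S_T, omega, seed and provenance
— the quantities the likelihood needs but the table does not hold.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ExperimentCondition
from .simulate import ProgressCurve

__all__ = [
    "write_progress_csv",
    "read_progress_csv",
    "write_draws_csv",
    "write_summary_json",
    "meta_path",
]


def meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_progress_csv(path, curves: Sequence[ProgressCurve],
                       time_unit: str = "s", conc_unit: str = "nM") -> None:
    """Write curves (one replicate per curve) plus the metadata sidecar.

    All curves must share one condition; heterogeneous conditions belong in
    separate files (one file = one experiment).
    """
    if not curves:
        raise ValueError("no curves to write")
    cond = curves[0].condition
    for c in curves[1:]:
        if (c.condition.E_T != cond.E_T or c.condition.S_T != cond.S_T
                or c.condition.omega != cond.omega):
            raise ValueError("curves in one file must share a condition")
    rows = []
    for rep, c in enumerate(curves):
        for t, p in zip(c.condition.t_obs, c.P_obs):
            rows.append((rep, t, int(p)))
    df = pd.DataFrame(rows, columns=["replicate", "time", "product"])
    # %.17g round-trips float64 exactly, so write -> read -> likelihood
    # is bit-identical to the in-memory evaluation
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "E_T": cond.E_T,
        "S_T": cond.S_T,
        "omega": cond.omega,
        "seed": [int(c.seed) for c in curves],
        "provenance": [c.provenance for c in curves],
        "time_unit": time_unit,
        "conc_unit": conc_unit,
    }
    meta_path(path).write_text(json.dumps(meta, indent=2))


def read_progress_csv(path) -> list[ProgressCurve]:
    """Read a progress-curve file back into validated ProgressCurve objects.

    Replicates split into separate curves.  Malformed files raise with the
    offending row named.
    """
    path = Path(path)
    mp = meta_path(path)
    if not mp.exists():
        raise FileNotFoundError(
            f"metadata sidecar {mp} not found; E_T, S_T and omega are "
            "required to interpret the counts")
    meta = json.loads(mp.read_text())
    for key in ("E_T", "S_T", "omega"):
        if key not in meta:
            raise ValueError(f"metadata sidecar {mp} is missing '{key}'")
    # round_trip parsing: the default fast parser is off by an ulp, which
    # would break bit-identical write -> read -> likelihood evaluation
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time", "product"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    seeds = meta.get("seed", [])
    provs = meta.get("provenance", [])
    curves = []
    for k, (rep, grp) in enumerate(df.groupby("replicate", sort=True)):
        t = grp["time"].to_numpy(dtype=float)
        p = grp["product"].to_numpy()
        rows = grp.index.to_numpy() + 2  # 1-based, counting the header line
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValueError(f"{path}: non-monotone time at row {rows[bad[0] + 1]} "
                             f"(replicate {rep})")
        if np.any(p < 0):
            r = rows[np.where(p < 0)[0][0]]
            raise ValueError(f"{path}: negative product count at row {r}")
        bad = np.where(np.diff(p) < 0)[0]
        if bad.size:
            raise ValueError(f"{path}: decreasing product count at row "
                             f"{rows[bad[0] + 1]} (replicate {rep})")
        cond = ExperimentCondition(E_T=float(meta["E_T"]), S_T=float(meta["S_T"]),
                                   omega=float(meta["omega"]), t_obs=t)
        curves.append(ProgressCurve(
            condition=cond, P_obs=p.astype(np.int64),
            provenance=(provs[k] if k < len(provs) else "file"),
            seed=(int(seeds[k]) if k < len(seeds) else 0)))
    return curves


def write_draws_csv(path, draws) -> None:
    """Posterior draws as CSV (iteration, k_cat and/or K_M columns)."""
    cols = {}
    n = None
    for name in ("k_cat", "K_M"):
        d = getattr(draws, name)
        if d is not None:
            cols[name] = d
            n = d.size
    if n is None:
        raise ValueError("draws hold no parameters")
    df = pd.DataFrame({"iteration": np.arange(n), **cols})
    df.to_csv(path, index=False)


def write_summary_json(path, summary: dict, settings: dict | None = None) -> None:
    """Summary JSON embedding the resolved settings and seed (provenance)."""
    out = dict(summary)
    if settings:
        out["settings"] = settings
    Path(path).write_text(json.dumps(out, indent=2))
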