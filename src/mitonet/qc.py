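"""Selective quality-control experiments: fusion:fission-ratio sweeps.

Two selective clearance mechanisms are compared over a grid of fusion-rate
multipliers (relative to the nominal parameterization):

* selective fusion (eps_f > 0): mutant molecules are excluded from the
  network, so they spend more time as mitophagy-susceptible singletons.
  Both extremes are inert -- a fully fused network has no mitophagy at all,
  and a fully fissioned one treats both genotypes identically -- so an
  intermediate fusion:fission ratio clears mutants best.
* selective mitophagy (eps_m > 0): mutant singletons are degraded faster,
  so the more fragmented the network the more mutants are exposed;
  complete fission is optimal.

Each sweep point is initialized on the neutral (eps_f = eps_m = 0)
steady-state line at the requested heteroplasmy and evaluated by the mean
heteroplasmy of a seeded SSA ensemble at a fixed horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams
from .deterministic import steady_state, InfeasibleParametersError
from .ssa import simulate_ensemble

__all__ = ["QCSweepResult", "qc_sweep", "find_optimum"]


@dataclass(frozen=True)
class QCSweepResult:
    """Mean final heteroplasmy along a fusion-rate grid for one selectivity."""

    ratio_grid: np.ndarray
    eps_f: float
    eps_m: float
    mean_h_final: np.ndarray       # surviving trajectories, fixed included
    se_h_final: np.ndarray
    mean_h_unfixed: np.ndarray     # excluding trajectories fixed at h=0 or 1
    p_extinct: np.ndarray
    feasible: np.ndarray
    n_iterations: int
    t_eval: float
    h0: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "eps_f": self.eps_f,
            "eps_m": self.eps_m,
            "ratio": self.ratio_grid,
            "mean_h": self.mean_h_final,
            "se_h": self.se_h_final,
            "mean_h_unfixed": self.mean_h_unfixed,
            "p_extinct": self.p_extinct,
            "feasible": self.feasible,
        })


def qc_sweep(base: ModelParams, selectivity: tuple, ratio_grid,
             t_eval: float = 1000.0, h0: float = 0.3, n_iter: int = 500,
             base_seed: int = 0) -> QCSweepResult:
    """Sweep the fusion rate multiplier for a fixed (eps_f, eps_m).

    For each ratio the fusion rate becomes ``gamma * M * (R * ratio)``; the
    initial state is the neutral steady state at that ratio (its copy number
    follows the steady-state line), selectivity is then switched on, and
    ``n_iter`` trajectories are run to ``t_eval``.  Infeasible grid points
    are flagged rather than fatal.
    """
    eps_f, eps_m = selectivity
    ratio_grid = np.asarray(ratio_grid, dtype=np.float64)
    if np.any(ratio_grid <= 0):
        raise ValueError("ratio grid values must be positive")
    if not 0.0 < h0 < 1.0:
        raise ValueError("h0 must lie in (0, 1)")
    k = ratio_grid.size
    mean_h = np.full(k, np.nan)
    se_h = np.full(k, np.nan)
    mean_h_unfixed = np.full(k, np.nan)
    p_ext = np.full(k, np.nan)
    feasible = np.zeros(k, dtype=bool)
    rec = np.array([0.0, t_eval])
    for i, ratio in enumerate(ratio_grid):
        neutral = base.with_(R=base.R * ratio, eps_f=0.0, eps_m=0.0)
        try:
            ss = steady_state(neutral, h0)
        except InfeasibleParametersError:
            continue
        feasible[i] = True
        x0 = ss.initial_copy_state()
        params = neutral.with_(eps_f=eps_f, eps_m=eps_m)
        ens = simulate_ensemble(x0, params, t_eval, rec, n_iter,
                                base_seed + 104729 * i)
        h = ens.h_matrix()[:, -1]
        alive = np.isfinite(h)
        hv = h[alive]
        p_ext[i] = 1.0 - hv.size / n_iter
        if hv.size:
            mean_h[i] = float(np.mean(hv))
            se_h[i] = float(np.std(hv, ddof=1) / np.sqrt(hv.size))
            unfixed = hv[(hv > 0.0) & (hv < 1.0)]
            mean_h_unfixed[i] = float(np.mean(unfixed)) if unfixed.size else np.nan
    return QCSweepResult(
        ratio_grid=ratio_grid, eps_f=float(eps_f), eps_m=float(eps_m),
        mean_h_final=mean_h, se_h_final=se_h, mean_h_unfixed=mean_h_unfixed,
        p_extinct=p_ext, feasible=feasible, n_iterations=n_iter,
        t_eval=float(t_eval), h0=float(h0),
    )


@dataclass(frozen=True)
class QCOptimum:
    ratio: float
    mean_h: float
    boundary: bool
    significant: bool


def find_optimum(result: QCSweepResult) -> QCOptimum:
    """Grid argmin of mean final heteroplasmy with a significance check.

    The optimum is called significant when its mean beats both feasible
    grid endpoints by more than 2 combined standard errors; a sweep that is
    flat within noise yields ``significant=False``.
    """
    ok = result.feasible & np.isfinite(result.mean_h_final)
    if ok.sum() < 3:
        raise ValueError("need at least 3 feasible grid points")
    idx = np.flatnonzero(ok)
    means = result.mean_h_final[idx]
    ses = result.se_h_final[idx]
    k = int(np.argmin(means))
    boundary = k in (0, idx.size - 1)
    significant = True
    for edge in (0, idx.size - 1):
        if edge == k:
            continue
        gap = means[edge] - means[k]
        if gap <= 2.0 * np.hypot(ses[edge], ses[k]):
            significant = False
    return QCOptimum(
        ratio=float(result.ratio_grid[idx[k]]),
        mean_h=float(means[k]),
        boundary=bool(boundary),
        significant=bool(significant),
    )
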