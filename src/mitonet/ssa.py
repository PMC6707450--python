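"""Exact stochastic simulation (Gillespie direct method) of the reaction network.

The inner loop is a numba-compiled kernel over the fixed channel ordering
defined in :mod:`mitonet.model`; a test pins the kernel's propensity vector to
the pure-Python reference.  Trajectories are recorded on a fixed time grid
with piecewise-constant semantics (the state at a record time is the state
after the last event at or before it).

Seeding: ensemble member ``i`` uses ``SeedSequence(base_seed).generate_state``
so ensembles are reproducible and order-independent, and a single (seed,
inputs) pair always yields a bit-identical trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import CopyState, ModelParams, stoichiometry_matrix

__all__ = ["Trajectory", "Ensemble", "simulate", "simulate_ensemble",
           "member_seeds"]


@njit(cache=True)
def _propensities_nb(ws, wf, ms, mf, pv, out):
    """Fill ``out`` with channel propensities; returns the total.

    pv layout: [gamma_w, gamma_m, beta, mu, b, kappa, delta, eps_m, mu_f,
    lam0, mode] with mode 0 = replication control, 1 = degradation control.
    """
    gw = pv[0]
    gm = pv[1]
    beta = pv[2]
    mu = pv[3]
    b = pv[4]
    kappa = pv[5]
    delta = pv[6]
    eps_m = pv[7]
    mu_f = pv[8]
    lam0 = pv[9]
    mode = pv[10]

    wT = ws + wf
    mT = ms + mf
    if mode == 0.0:
        lam = mu + b * (kappa - (wT + delta * mT))
        if lam < 0.0:
            lam = 0.0
        dw = mu
    else:
        lam = lam0
        dw = lam0 + b * ((wT + delta * mT) - kappa)
        if dw < 0.0:
            dw = 0.0
    dm = dw * (1.0 + eps_m)

    out[0] = gw * ws * (ws - 1.0) * 0.5
    out[1] = gw * wf * ws
    out[2] = beta * wf
    out[3] = gm * ms * (ms - 1.0) * 0.5
    out[4] = gm * mf * ms
    out[5] = beta * mf
    out[6] = lam * ws
    out[7] = lam * wf
    out[8] = dw * ws
    out[9] = lam * ms
    out[10] = lam * mf
    out[11] = dm * ms
    out[12] = gm * wf * ms
    out[13] = gm * mf * ws
    out[14] = gm * ws * ms
    total = 0.0
    for i in range(15):
        total += out[i]
    if out.shape[0] > 15:
        out[15] = mu_f * wf
        out[16] = mu_f * mf
        total += out[15] + out[16]
    return total


@njit(cache=True)
def _ssa_run(x0, rec_times, pv, stoich, seed, out_states):
    """Direct-method SSA from x0, recording on rec_times (sorted, >= 0)."""
    np.random.seed(seed)
    ws = float(x0[0])
    wf = float(x0[1])
    ms = float(x0[2])
    mf = float(x0[3])
    n_ch = stoich.shape[0]
    props = np.empty(n_ch, dtype=np.float64)
    n_rec = rec_times.shape[0]
    t = 0.0
    i_rec = 0
    # record any grid points at t == 0
    while i_rec < n_rec and rec_times[i_rec] <= t:
        out_states[i_rec, 0] = int(ws)
        out_states[i_rec, 1] = int(wf)
        out_states[i_rec, 2] = int(ms)
        out_states[i_rec, 3] = int(mf)
        i_rec += 1
    while i_rec < n_rec:
        total = _propensities_nb(ws, wf, ms, mf, pv, props)
        if total <= 0.0:
            # frozen (possibly extinct) state: fill remaining records
            while i_rec < n_rec:
                out_states[i_rec, 0] = int(ws)
                out_states[i_rec, 1] = int(wf)
                out_states[i_rec, 2] = int(ms)
                out_states[i_rec, 3] = int(mf)
                i_rec += 1
            break
        t_next = t + (-np.log(np.random.random())) / total
        while i_rec < n_rec and rec_times[i_rec] < t_next:
            out_states[i_rec, 0] = int(ws)
            out_states[i_rec, 1] = int(wf)
            out_states[i_rec, 2] = int(ms)
            out_states[i_rec, 3] = int(mf)
            i_rec += 1
        if i_rec >= n_rec:
            break
        t = t_next
        r = np.random.random() * total
        acc = 0.0
        k = n_ch - 1
        for j in range(n_ch):
            acc += props[j]
            if r < acc:
                k = j
                break
        ws += stoich[k, 0]
        wf += stoich[k, 1]
        ms += stoich[k, 2]
        mf += stoich[k, 3]


@dataclass(frozen=True)
class Trajectory:
    """A single recorded SSA trajectory."""

    record_times: np.ndarray
    states: np.ndarray  # (n_rec, 4) int64
    seed: int

    def heteroplasmy(self) -> np.ndarray:
        """h at each record time (NaN where the cell is extinct)."""
        n = self.states.sum(axis=1).astype(np.float64)
        m = self.states[:, 2] + self.states[:, 3]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, m / n, np.nan)


@dataclass(frozen=True)
class Ensemble:
    """A seeded collection of trajectories sharing one record grid."""

    record_times: np.ndarray
    states: np.ndarray  # (n_traj, n_rec, 4) int64
    seeds: np.ndarray
    params: ModelParams

    @property
    def n_traj(self) -> int:
        return self.states.shape[0]

    def copy_numbers(self) -> np.ndarray:
        return self.states.sum(axis=2).astype(np.float64)

    def h_matrix(self) -> np.ndarray:
        """(n_traj, n_rec) heteroplasmy; NaN for extinct (n=0) cells."""
        n = self.copy_numbers()
        m = (self.states[:, :, 2] + self.states[:, :, 3]).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, m / n, np.nan)

    def summary(self):
        """Per-timepoint summary statistics over surviving (n>0) trajectories.

        Columns: t, Eh, Vh, En, Vn, p_fix0, p_fix1, p_extinct, n_surviving.
        Heteroplasmy moments are over surviving cells (h is undefined at
        n=0); fixation fractions are among survivors and extinction is
        reported separately.
        """
        import pandas as pd

        h = self.h_matrix()
        n = self.copy_numbers()
        alive = n > 0
        n_alive = alive.sum(axis=0)
        rows = []
        for j, t in enumerate(self.record_times):
            hj = h[alive[:, j], j]
            k = hj.size
            rows.append({
                "t": float(t),
                "Eh": float(np.mean(hj)) if k else np.nan,
                "Vh": float(np.var(hj, ddof=1)) if k > 1 else np.nan,
                "En": float(np.mean(n[alive[:, j], j])) if k else np.nan,
                "Vn": float(np.var(n[alive[:, j], j], ddof=1)) if k > 1 else np.nan,
                "p_fix0": float(np.mean(hj == 0.0)) if k else np.nan,
                "p_fix1": float(np.mean(hj == 1.0)) if k else np.nan,
                "p_extinct": float(1.0 - k / self.n_traj),
                "n_surviving": int(k),
            })
        return pd.DataFrame(rows)

    def to_long_frame(self):
        """Long-format trajectory table (traj_id, t, ws, wf, ms, mf)."""
        import pandas as pd

        n_traj, n_rec, _ = self.states.shape
        return pd.DataFrame({
            "traj_id": np.repeat(np.arange(n_traj), n_rec),
            "t": np.tile(self.record_times, n_traj),
            "ws": self.states[:, :, 0].ravel(),
            "wf": self.states[:, :, 1].ravel(),
            "ms": self.states[:, :, 2].ravel(),
            "mf": self.states[:, :, 3].ravel(),
        })


def _check_record_times(record_times, t_max):
    rt = np.asarray(record_times, dtype=np.float64)
    if rt.ndim != 1 or rt.size == 0:
        raise ValueError("record_times must be a non-empty 1-d sequence")
    if np.any(np.diff(rt) < 0):
        raise ValueError("record_times must be non-decreasing")
    if rt[0] < 0 or rt[-1] > t_max:
        raise ValueError("record_times must lie within [0, t_max]")
    return rt


def member_seeds(base_seed: int, n_traj: int) -> np.ndarray:
    """Deterministic per-member seeds derived from a base seed."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n_traj, dtype=np.uint32) % np.uint32(2**31)).astype(np.int64)


def simulate(state0: CopyState, params: ModelParams, t_max: float,
             record_times, seed: int) -> Trajectory:
    """Run one exact SSA trajectory, recording on a fixed grid.

    If the total propensity reaches zero the state is frozen thereafter
    (an empty cell is recorded as extinct, not an error).
    """
    rt = _check_record_times(record_times, t_max)
    if isinstance(state0, CopyState):
        x0 = state0.as_array()
    else:
        x0 = np.asarray(state0, dtype=np.int64)
        CopyState.from_array(x0)  # validates non-negativity
    pv = params.to_vector()
    stoich = stoichiometry_matrix(params)
    out = np.empty((rt.size, 4), dtype=np.int64)
    _ssa_run(x0, rt, pv, stoich, np.int64(seed), out)
    return Trajectory(record_times=rt, states=out, seed=int(seed))


def simulate_ensemble(state0: CopyState, params: ModelParams, t_max: float,
                      record_times, n_traj: int, base_seed: int) -> Ensemble:
    """Run ``n_traj`` independent trajectories with derived member seeds."""
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    rt = _check_record_times(record_times, t_max)
    x0 = state0.as_array() if isinstance(state0, CopyState) else np.asarray(state0, np.int64)
    pv = params.to_vector()
    stoich = stoichiometry_matrix(params)
    seeds = member_seeds(base_seed, n_traj)
    states = np.empty((n_traj, rt.size, 4), dtype=np.int64)
    for i in range(n_traj):
        _ssa_run(x0, rt, pv, stoich, seeds[i], states[i])
    return Ensemble(record_times=rt, states=states, seeds=seeds, params=params)
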