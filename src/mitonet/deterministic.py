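"""Mean-field ODE system, integration, and the line of steady states.

Converting the reaction channels into mass-action ODEs (with the large-n
substitution x(x-1) -> x^2 in pair-fusion terms) gives four coupled equations
for (ws, wf, ms, mf).  For the neutral model the system relaxes to a
one-parameter family of fixed points indexed by heteroplasmy h -- the "line of
steady states" -- characterized by:

* turnover balance      lambda(x_ss) = mu * fs(x_ss)   (replication control)
* singleton-flux balance gamma*n*fs + (lambda+mu)*fs = beta*(1-fs)
* the control line       lambda = mu + b*(kappa - (wT + delta*mT))

The steady-state solver reduces the neutral system to a single bracketed root
find in fs (exact under genotype symmetry), then distributes copy numbers by
the target heteroplasmy; every returned state is verified against the full
ODE right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import (
    CopyState,
    ModelParams,
    propensity_vector,
    stoichiometry_matrix,
    heteroplasmy,
    singleton_fraction,
)

__all__ = ["SteadyState", "ode_rhs", "integrate", "steady_state",
           "steady_state_line", "steady_state_line_frame"]

RESIDUAL_RTOL = 1e-8  # |rhs| < RESIDUAL_RTOL * n_ss on any returned steady state


class InfeasibleParametersError(ValueError):
    """No positive steady state exists for the given parameterization."""


@dataclass(frozen=True)
class SteadyState:
    """A point on the deterministic steady-state line."""

    state: np.ndarray  # real-valued (ws, wf, ms, mf)
    n_ss: float
    fs_ss: float
    h_ss: float

    def initial_copy_state(self) -> CopyState:
        """Round to an integer CopyState for initializing stochastic runs."""
        return CopyState.from_array(np.rint(self.state).astype(np.int64))


def ode_rhs(state, params: ModelParams) -> np.ndarray:
    """Mean-field time derivative: sum over channels of stoich * propensity."""
    x = np.asarray(state, dtype=np.float64)
    S = stoichiometry_matrix(params)
    a = propensity_vector(x, params, deterministic=True)
    return S.T @ a


def integrate(state0, params: ModelParams, t_grid) -> np.ndarray:
    """Integrate the mean-field ODEs on an increasing time grid.

    Returns an array of shape (len(t_grid), 4).  Uses a stiff-safe solver
    (LSODA) at tight tolerance; tiny negative round-off is clipped to zero.
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    x0 = np.asarray(state0, dtype=np.float64)
    t_span = (min(0.0, float(t_grid[0])), float(t_grid[-1]))
    sol = solve_ivp(
        lambda t, x: ode_rhs(x, params), t_span, x0,
        t_eval=t_grid, method="LSODA", rtol=1e-10, atol=1e-8,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed: {sol.message} (nfev={sol.nfev}, "
            f"last t={sol.t[-1] if len(sol.t) else 'none'})"
        )
    return np.clip(sol.y.T, 0.0, None)


def _state_at(fs: float, n: float, h: float) -> np.ndarray:
    w, m = (1.0 - h) * n, h * n
    return np.array([fs * w, (1.0 - fs) * w, fs * m, (1.0 - fs) * m])


def _is_stable(x: np.ndarray, params: ModelParams) -> bool:
    """Linear stability of a steady state, ignoring the zero mode along the
    steady-state line (numerical Jacobian, central differences)."""
    scale = max(float(np.sum(x)), 1.0)
    eps = 1e-5 * scale
    J = np.empty((4, 4))
    for j in range(4):
        dx = np.zeros(4)
        dx[j] = eps
        J[:, j] = (ode_rhs(x + dx, params) - ode_rhs(x - dx, params)) / (2 * eps)
    re = np.sort(np.linalg.eigvals(J).real)
    # the largest eigenvalue is the ~zero drift mode along the line
    return bool(re[-1] < 1e-7 and np.all(re[:-1] < 1e-7))


def _solve_fs(F, n_of_fs, params: ModelParams, h_target: float,
              lo: float, hi: float) -> float:
    """All roots of the singleton-flux balance on (lo, hi); pick the
    dynamically stable one.

    In the nominal regime the root is unique, but with turnover fast
    relative to the feedback strength the balance can admit an additional,
    unstable solution.
    """
    grid = np.linspace(lo, hi, 513)
    vals = np.array([F(f) for f in grid])
    roots = []
    for a, b_, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(F, a, b_, xtol=1e-14, rtol=1e-14)))
    roots = [r for r in roots if n_of_fs(r) > 0]
    if not roots:
        raise InfeasibleParametersError(
            "no positive steady state: singleton-flux balance has no root"
        )
    if len(roots) == 1:
        return roots[0]
    stable = [r for r in roots
              if _is_stable(_state_at(r, n_of_fs(r), h_target), params)]
    if not stable:
        raise InfeasibleParametersError(
            f"{len(roots)} steady-state candidates, none dynamically stable"
        )
    # deterministic tie-break: the largest-copy-number stable branch
    return max(stable, key=n_of_fs)


def steady_state(params: ModelParams, h_target: float) -> SteadyState:
    """Solve the neutral steady state at the requested heteroplasmy.

    Only defined for the neutral model (eps_f = eps_m = 0, mu_f = 0), where
    the genotype-symmetric reduction to (n, fs) is exact.
    """
    if params.eps_f != 0 or params.eps_m != 0 or params.mu_f != 0:
        raise InfeasibleParametersError(
            "steady-state line is defined for the neutral model "
            "(eps_f = eps_m = mu_f = 0)"
        )
    if not 0.0 <= h_target <= 1.0:
        raise ValueError("h_target must lie in [0, 1]")
    u = 1.0 - h_target + params.delta * h_target
    g = params.gamma_eff
    beta = params.beta_eff

    if params.control_mode == "replication":
        mu, b = params.mu, params.b

        def n_of_fs(fs):
            # control line: mu*fs = mu + b*(kappa - n*u)
            return (params.kappa + (1.0 - fs) * mu / b) / u

        def F(fs):
            n = n_of_fs(fs)
            return g * n * fs + mu * (1.0 + fs) * fs - beta * (1.0 - fs)

        if beta == 0.0:
            fs_ss = 0.0
            n_ss = n_of_fs(0.0)
        else:
            fs_ss = _solve_fs(F, n_of_fs, params, h_target, lo=1e-12, hi=1.0)
            n_ss = n_of_fs(fs_ss)
    else:  # degradation control
        lam0, b = params.lam0, params.b

        def n_of_fs(fs):
            # control line: lam0/fs = lam0 + b*(n*u - kappa)
            return (params.kappa + lam0 * (1.0 - fs) / (b * fs)) / u

        def F(fs):
            n = n_of_fs(fs)
            return g * n * fs + lam0 * (1.0 + fs) - beta * (1.0 - fs)

        fs_ss = _solve_fs(F, n_of_fs, params, h_target, lo=1e-9, hi=1.0 - 1e-12)
        n_ss = n_of_fs(fs_ss)

    if n_ss <= 0:
        raise InfeasibleParametersError(f"steady state has n_ss={n_ss:.3g} <= 0")

    x = _state_at(fs_ss, n_ss, h_target)
    resid = np.max(np.abs(ode_rhs(x, params)))
    if resid > RESIDUAL_RTOL * max(n_ss, 1.0):
        raise InfeasibleParametersError(
            f"steady-state residual {resid:.3g} exceeds tolerance "
            f"{RESIDUAL_RTOL * max(n_ss, 1.0):.3g}"
        )
    return SteadyState(state=x, n_ss=float(n_ss), fs_ss=float(fs_ss),
                       h_ss=float(h_target))


def steady_state_line(params: ModelParams, h_grid) -> list:
    """One SteadyState per heteroplasmy in h_grid (the line of steady states).

    For delta = 1 every point shares the same total copy number; for
    delta < 1 mutants contribute less to the feedback, so n_ss grows with h.
    """
    return [steady_state(params, float(h)) for h in h_grid]


def steady_state_line_frame(params: ModelParams, h_grid):
    """Steady-state line as a pandas DataFrame (h, ws, wf, ms, mf, n, fs)."""
    import pandas as pd

    rows = []
    for ss in steady_state_line(params, h_grid):
        ws, wf, ms, mf = ss.state
        rows.append({"h": ss.h_ss, "ws": ws, "wf": wf, "ms": ms, "mf": mf,
                     "n": ss.n_ss, "fs": ss.fs_ss})
    return pd.DataFrame(rows)
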