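"""Heteroplasmy-variance analytics: closed-form prediction, slope fitting,
the relative error metric, and quasi-stationarity checks.

In the quasi-stationary regime (negligible fixation of either allele) the
variance of heteroplasmy grows linearly:

    V(h) ~ (2 mu fs / n) * h (1 - h) * t        (replication control)
    V(h) ~ (2 lam0 / n)  * h (1 - h) * t        (degradation control)

evaluated at the deterministic steady state.  Under replication control the
turnover rate seen by the population is set by mitophagy of singletons, so
the drift clock is rescaled by the fraction of unfused molecules fs and is
independent of the absolute fission-fusion rate magnitude; under degradation
control every molecule replicates at the constant rate lam0 and the network
dependence disappears.

The accuracy of the prediction is summarized by the relative error

    epsilon = | 1 - Vdot_theory / E_t[Vdot_sim] |

where Vdot_sim are finite-difference estimates of dV/dt on the record grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams
from .deterministic import SteadyState
from .ssa import Ensemble

__all__ = [
    "VariancePrediction", "VarianceFit", "normalized_theory_slope",
    "predicted_variance", "variance_slope", "error_metric",
    "quasi_stationarity_check", "bootstrap_slope_ci",
]


@dataclass(frozen=True)
class VariancePrediction:
    slope_normalized: float  # dV/dt / (h(1-h)), per day
    times: np.ndarray
    curve: np.ndarray
    regime: str


@dataclass(frozen=True)
class VarianceFit:
    slope_sim: float          # through-origin slope of V(h) vs t
    window: tuple             # (t_lo, t_hi) actually used
    vdot_sim: np.ndarray      # finite-difference dV/dt estimates in window
    epsilon: float | None     # filled when a theory slope was supplied
    valid: bool               # fixation fraction below threshold in window


def normalized_theory_slope(ss: SteadyState, params: ModelParams) -> float:
    """Predicted dV(h)/dt divided by h(1-h), at the steady state."""
    if params.control_mode == "replication":
        return 2.0 * params.mu * ss.fs_ss / ss.n_ss
    return 2.0 * params.lam0 / ss.n_ss


def predicted_variance(t, ss: SteadyState, params: ModelParams) -> VariancePrediction:
    """Closed-form V(h) prediction on a time grid, evaluated at ``ss``."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    slope_norm = normalized_theory_slope(ss, params)
    curve = slope_norm * ss.h_ss * (1.0 - ss.h_ss) * t
    regime = (
        "replication_control" if params.control_mode == "replication"
        else "degradation_control"
    )
    return VariancePrediction(
        slope_normalized=float(slope_norm), times=t, curve=curve, regime=regime
    )


def _vh_table(ensemble_or_summary) -> pd.DataFrame:
    if isinstance(ensemble_or_summary, Ensemble):
        return ensemble_or_summary.summary()
    df = ensemble_or_summary
    if "t" not in df.columns or "Vh" not in df.columns:
        raise ValueError("summary table needs columns 't' and 'Vh'")
    return df


def variance_slope(ensemble_or_summary, window=None, theory_slope=None,
                   fixation_threshold: float = 0.01) -> VarianceFit:
    """Fit the through-origin slope of V(h) versus t.

    Accepts an :class:`Ensemble` or a summary DataFrame with columns
    ``t``/``Vh`` (and optionally ``p_fix0``/``p_fix1`` for the validity
    check).  ``window=(t_lo, t_hi)`` restricts the fit; by default all
    record times with fixation fraction below ``fixation_threshold`` are
    used.  Regression is through the origin because V(h, 0) = 0 by
    construction.  If ``theory_slope`` (a dV/dt, same units as the fit) is
    given, the error metric epsilon is attached.
    """
    df = _vh_table(ensemble_or_summary)
    t = df["t"].to_numpy(dtype=float)
    v = df["Vh"].to_numpy(dtype=float)
    if {"p_fix0", "p_fix1"} <= set(df.columns):
        p_fixed = df["p_fix0"].to_numpy(float) + df["p_fix1"].to_numpy(float)
    else:
        p_fixed = np.zeros_like(t)

    mask = (t > 0) & np.isfinite(v)
    if window is not None:
        t_lo, t_hi = window
        mask &= (t >= t_lo) & (t <= t_hi)
    else:
        mask &= p_fixed <= fixation_threshold
    if mask.sum() < 2:
        raise ValueError("fewer than 2 usable record times in fit window")
    valid = bool(np.all(p_fixed[mask] <= fixation_threshold))

    tt, vv = t[mask], v[mask]
    slope = float(np.sum(tt * vv) / np.sum(tt * tt))

    # finite-difference dV/dt estimates including the origin
    t_fd = np.concatenate([[0.0], tt])
    v_fd = np.concatenate([[0.0], vv])
    vdot = np.diff(v_fd) / np.diff(t_fd)

    eps = None
    if theory_slope is not None:
        eps = error_metric(theory_slope, vdot)
    return VarianceFit(slope_sim=slope, window=(float(tt[0]), float(tt[-1])),
                       vdot_sim=vdot, epsilon=eps, valid=valid)


def error_metric(theory_slope: float, sim_slopes) -> float:
    """Relative error |1 - theory / mean_t(sim)| between predicted and
    simulated variance growth rates."""
    sim_slopes = np.asarray(sim_slopes, dtype=np.float64)
    mean_sim = float(np.mean(sim_slopes))
    if mean_sim == 0.0:
        raise ZeroDivisionError("mean simulated variance slope is zero")
    return abs(1.0 - theory_slope / mean_sim)


def quasi_stationarity_check(ensemble_or_summary, threshold: float = 0.01) -> pd.DataFrame:
    """Flag record times where the fixation fraction P(h=0)+P(h=1) exceeds
    ``threshold``; linear-variance comparisons are invalid beyond that."""
    df = _vh_table(ensemble_or_summary)
    p_fixed = df.get("p_fix0", 0.0) + df.get("p_fix1", 0.0)
    out = pd.DataFrame({"t": df["t"], "p_fixed": p_fixed})
    out["valid"] = out["p_fixed"] <= threshold
    return out


def bootstrap_slope_ci(ensemble: Ensemble, window=None, n_boot: int = 200,
                       seed: int = 0, ci: float = 0.95) -> tuple:
    """Percentile bootstrap CI for the fitted V(h) slope, resampling
    trajectories with replacement."""
    rng = np.random.default_rng(seed)
    h = ensemble.h_matrix()
    t = ensemble.record_times
    n_traj = h.shape[0]
    base = variance_slope(ensemble, window=window)
    t_lo, t_hi = base.window
    jmask = (t >= t_lo) & (t <= t_hi)
    tt = t[jmask]
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_traj, n_traj)
        hb = h[idx][:, jmask]
        vv = np.nanvar(hb, axis=0, ddof=1)
        slopes[b] = np.sum(tt * vv) / np.sum(tt * tt)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(slopes, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
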