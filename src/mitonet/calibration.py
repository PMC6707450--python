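"""Calibration of nominal parameterizations from steady-state targets.

The biologically motivated operating point is a cell with total copy number
n ~ 1000, half of the mtDNAs unfused (fs = 0.5), mitophagy rate mu = 0.023/day,
and network dynamics roughly 10^3-fold faster than turnover (beta/mu ~ 1000).
Rather than hard-coding rate constants, the fusion rate gamma and the control
parameter kappa are solved from the closed-form deterministic balance
conditions so that the steady state hits the requested (n, fs) exactly at the
requested network-rate magnitude M and ratio R.

Balance conditions at the steady state (neutral model, singleton->fused
replication topology, s = fs*n singletons, f = (1-fs)*n fused):

* turnover:       lambda_ss * n = mu * s          => lambda_ss = mu * fs
* singleton flux: gamma*n*s + (lambda_ss + mu)*s = beta*f
* control line:   lambda_ss = mu + b*(kappa - n)   (delta = 1)

Under degradation control the replication rate is a constant lam0 and the
per-singleton mitophagy rate carries the feedback; the analogous balances are
mu_ss = lam0/fs and gamma*n*fs + lam0*(1+fs) = beta*(1-fs).
"""

from __future__ import annotations

from .model import ModelParams

__all__ = ["calibrate_replication_control", "calibrate_degradation_control"]


def calibrate_replication_control(
    mu: float = 0.023,
    n_target: float = 1000.0,
    fs_target: float = 0.5,
    beta_over_mu: float = 1000.0,
    b: float = 1e-4,
    delta: float = 1.0,
    M: float = 1.0,
    R: float = 1.0,
    **extra,
) -> ModelParams:
    """Solve (gamma, kappa) so the deterministic steady state sits at the
    requested copy number and singleton fraction.

    The returned ``gamma``/``beta`` are base rates: the effective rates are
    ``gamma*M*R`` and ``beta*M``, and the calibration is performed at the
    requested (M, R), so the steady-state targets hold for those multipliers.
    """
    if not 0 < fs_target < 1:
        raise ValueError("fs_target must be in (0,1)")
    if b <= 0 or mu <= 0 or n_target <= 0:
        raise ValueError("mu, b, n_target must be positive")
    beta0 = beta_over_mu * mu
    beta_eff = beta0 * M
    lam_ss = mu * fs_target
    # singleton-flux balance, divided through by n:
    #   gamma_eff * n * fs + mu * (1 + fs) * fs = beta_eff * (1 - fs)
    num = beta_eff * (1.0 - fs_target) - mu * (1.0 + fs_target) * fs_target
    if num <= 0:
        raise ValueError(
            "infeasible calibration: fission flux cannot balance turnover "
            f"(beta_eff*(1-fs)={beta_eff * (1 - fs_target):.3g} too small)"
        )
    gamma_eff = num / (n_target * fs_target)
    gamma0 = gamma_eff / (M * R)
    # control line at delta=1: lam_ss = mu + b*(kappa - n)
    kappa = n_target - (mu - lam_ss) / b
    return ModelParams(
        gamma=gamma0, beta=beta0, mu=mu, b=b, kappa=kappa, delta=delta,
        M=M, R=R, control_mode="replication", **extra,
    )


def calibrate_degradation_control(
    lam0: float = 0.0115,
    n_target: float = 1000.0,
    fs_target: float = 0.5,
    beta: float = 23.0,
    b: float = 1e-4,
    delta: float = 1.0,
    M: float = 1.0,
    R: float = 1.0,
    **extra,
) -> ModelParams:
    """Degradation-control analogue: constant replication rate ``lam0``,
    feedback in the per-singleton mitophagy rate; solve (gamma, kappa) for
    the requested (n, fs)."""
    if not 0 < fs_target < 1:
        raise ValueError("fs_target must be in (0,1)")
    beta_eff = beta * M
    # singleton-flux balance with mu_ss = lam0/fs:
    #   gamma_eff*n*fs + lam0*fs + lam0 = beta_eff*(1-fs)
    num = beta_eff * (1.0 - fs_target) - lam0 * (1.0 + fs_target)
    if num <= 0:
        raise ValueError("infeasible calibration for degradation control")
    gamma_eff = num / (n_target * fs_target)
    gamma0 = gamma_eff / (M * R)
    # control line: lam0/fs = lam0 + b*(n - kappa)
    kappa = n_target - lam0 * (1.0 - fs_target) / (b * fs_target)
    return ModelParams(
        gamma=gamma0, beta=beta, mu=0.0, b=b, kappa=kappa, delta=delta,
        M=M, R=R, control_mode="degradation", lam0=lam0, **extra,
    )
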