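"""Domain types and the coupled network-genetic reaction system.

Each mtDNA molecule carries a genotype (wild type ``W`` or mutant ``M``) and a
network state (singleton ``S``, i.e. in an unfused mitochondrial fragment, or
fused ``F``).  The cell state is the copy-number vector ``(ws, wf, ms, mf)``.

Three blocks of reactions couple the physical and genetic dynamics:

* network processes -- fusion of two singletons, fusion of a singleton onto a
  fused molecule, and fission of a fused molecule back to a singleton, for each
  genotype (6 channels);
* genetic processes -- replication of singletons and of fused molecules, and
  mitophagy of singletons (only unfused mitochondria are degraded), for each
  genotype (6 channels);
* cross processes -- fusion events pairing the two genotypes (3 channels).

That gives the canonical 15-channel network; allowing a nonzero degradation
rate for fused species adds 2 optional channels.

Copy number is fed back through a linear replication rate
``lambda = mu + b*(kappa - (wT + delta*mT))`` (replication control) or, in the
alternative control mode, through a mirror-image linear mitophagy rate with the
replication rate held constant (degradation control).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Literal

import numpy as np

__all__ = [
    "CopyState",
    "ModelParams",
    "Reaction",
    "ReactionNetwork",
    "heteroplasmy",
    "folded_heteroplasmy",
    "singleton_fraction",
    "replication_rate",
    "degradation_rate",
    "build_reaction_network",
    "propensities",
    "propensity_vector",
    "stoichiometry_matrix",
    "N_CORE_CHANNELS",
]

N_CORE_CHANNELS = 15

SPECIES = ("ws", "wf", "ms", "mf")


class UndefinedStateError(ValueError):
    """Raised when a per-cell statistic is requested for an empty cell (n=0)."""


@dataclass(frozen=True)
class CopyState:
    """Copy numbers of the four molecular species (non-negative integers)."""

    ws: int
    wf: int
    ms: int
    mf: int

    def __post_init__(self) -> None:
        for name in SPECIES:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n(self) -> int:
        """Total mtDNA copy number."""
        return self.ws + self.wf + self.ms + self.mf

    @property
    def w_total(self) -> int:
        return self.ws + self.wf

    @property
    def m_total(self) -> int:
        return self.ms + self.mf

    def as_array(self) -> np.ndarray:
        return np.array([self.ws, self.wf, self.ms, self.mf], dtype=np.int64)

    @classmethod
    def from_array(cls, x) -> "CopyState":
        ws, wf, ms, mf = (int(v) for v in x)
        return cls(ws, wf, ms, mf)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and control-law parameters (time unit: days).

    Parameters
    ----------
    gamma : float
        Nominal fusion stochastic rate constant (per molecule-pair per day).
    beta : float
        Nominal fission rate constant (per fused molecule per day).
    mu : float
        Mitophagy rate (per singleton per day) under replication control.
    b : float
        Copy-number control strength (per molecule per day).
    kappa : float
        Target-copy-number parameter (molecules); indicative of, but not
        equal to, the steady-state copy number.
    delta : float
        Relative contribution of mutant molecules to the control strength
        ("maintenance of wild type": delta < 1 gives mutants a higher
        carrying capacity).
    eps_f : float
        Fusion selectivity; fusion channels involving >=1 mutant run at
        ``gamma / (1 + eps_f)``.
    eps_m : float
        Mitophagy selectivity; mutant singletons are degraded at
        ``mu * (1 + eps_m)``.
    mu_f : float
        Optional degradation rate for fused species (default 0: only
        singletons are susceptible to mitophagy).
    control_mode : {"replication", "degradation"}
        Whether copy number is controlled through the replication rate
        (state-dependent lambda, constant mu) or through the degradation
        rate (constant lam0, state-dependent mu).
    replication_topology : {"singleton_to_fused", "singleton_to_singleton"}
        Whether replication of a singleton yields two fused molecules
        (replication happens inside one organelle) or two singletons
        (replication tied to fission).
    M, R : float
        Network-rate magnitude and fusion:fission ratio multipliers; the
        effective rates are ``gamma*M*R`` and ``beta*M``.
    lam0 : float
        Constant replication rate used only under degradation control.
    """

    gamma: float
    beta: float
    mu: float
    b: float
    kappa: float
    delta: float = 1.0
    eps_f: float = 0.0
    eps_m: float = 0.0
    mu_f: float = 0.0
    control_mode: Literal["replication", "degradation"] = "replication"
    replication_topology: Literal[
        "singleton_to_fused", "singleton_to_singleton"
    ] = "singleton_to_fused"
    M: float = 1.0
    R: float = 1.0
    lam0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma", "beta", "mu", "b", "eps_f", "eps_m", "mu_f",
                     "delta", "M", "R", "lam0"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.control_mode not in ("replication", "degradation"):
            raise ValueError(f"unknown control_mode {self.control_mode!r}")
        if self.replication_topology not in (
            "singleton_to_fused", "singleton_to_singleton"
        ):
            raise ValueError(
                f"unknown replication_topology {self.replication_topology!r}"
            )
        if self.control_mode == "degradation" and self.lam0 <= 0:
            raise ValueError("degradation control requires lam0 > 0")

    # effective rates after magnitude/ratio reparameterization
    @property
    def gamma_eff(self) -> float:
        """Effective wild-type fusion rate gamma * M * R."""
        return self.gamma * self.M * self.R

    @property
    def gamma_mut(self) -> float:
        """Effective fusion rate for channels involving >=1 mutant."""
        return self.gamma_eff / (1.0 + self.eps_f)

    @property
    def beta_eff(self) -> float:
        """Effective fission rate beta * M."""
        return self.beta * self.M

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_vector(self) -> np.ndarray:
        """Pack the numeric parameters for the compiled SSA kernel."""
        mode = 0.0 if self.control_mode == "replication" else 1.0
        return np.array(
            [self.gamma_eff, self.gamma_mut, self.beta_eff, self.mu, self.b,
             self.kappa, self.delta, self.eps_m, self.mu_f, self.lam0, mode],
            dtype=np.float64,
        )


# ---------------------------------------------------------------------------
# per-cell statistics

def _total(state) -> tuple:
    if isinstance(state, CopyState):
        return state.ws, state.wf, state.ms, state.mf
    ws, wf, ms, mf = state
    return ws, wf, ms, mf


def heteroplasmy(state) -> float:
    """Mutant-allele fraction h = (ms+mf)/n.  Requires n > 0."""
    ws, wf, ms, mf = _total(state)
    n = ws + wf + ms + mf
    if n <= 0:
        raise UndefinedStateError("heteroplasmy undefined for an empty cell")
    return (ms + mf) / n


def folded_heteroplasmy(state) -> float:
    """Allele-frequency-folded heteroplasmy 0.5 - |h - 0.5|, in [0, 0.5]."""
    return 0.5 - abs(heteroplasmy(state) - 0.5)


def singleton_fraction(state) -> float:
    """Fraction of mtDNAs in unfused organelles, fs = (ws+ms)/n."""
    ws, wf, ms, mf = _total(state)
    n = ws + wf + ms + mf
    if n <= 0:
        raise UndefinedStateError("singleton fraction undefined for an empty cell")
    return (ws + ms) / n


# ---------------------------------------------------------------------------
# rate laws

def replication_rate(state, params: ModelParams) -> float:
    """Per-molecule replication rate lambda.

    Under replication control this is the linear feedback law
    ``max(0, mu + b*(kappa - (wT + delta*mT)))``; the clamp keeps the
    propensity non-negative at large copy numbers.  Under degradation control
    the replication rate is the constant ``lam0``.
    """
    if params.control_mode == "degradation":
        return params.lam0
    ws, wf, ms, mf = _total(state)
    wT, mT = ws + wf, ms + mf
    return max(0.0, params.mu + params.b * (params.kappa - (wT + params.delta * mT)))


def degradation_rate(state, params: ModelParams, genotype: str) -> float:
    """Per-singleton mitophagy rate for genotype ``"W"`` or ``"M"``.

    Replication control: constant ``mu`` (times ``1+eps_m`` for mutants).
    Degradation control: mirror-image linear law
    ``max(0, lam0 + b*(wT + delta*mT - kappa))`` (times ``1+eps_m`` for
    mutants).
    """
    if genotype not in ("W", "M"):
        raise ValueError("genotype must be 'W' or 'M'")
    sel = (1.0 + params.eps_m) if genotype == "M" else 1.0
    if params.control_mode == "replication":
        return params.mu * sel
    ws, wf, ms, mf = _total(state)
    wT, mT = ws + wf, ms + mf
    base = max(0.0, params.lam0 + params.b * ((wT + params.delta * mT) - params.kappa))
    return base * sel


# ---------------------------------------------------------------------------
# reaction network

@dataclass(frozen=True)
class Reaction:
    label: str
    stoich: tuple  # signed change to (ws, wf, ms, mf)
    propensity: Callable[[CopyState, ModelParams], float]


@dataclass(frozen=True)
class ReactionNetwork:
    reactions: tuple

    def __len__(self) -> int:
        return len(self.reactions)

    @property
    def labels(self) -> list:
        return [r.label for r in self.reactions]


def _channel_table(params: ModelParams):
    """(label, stoich, propensity-expression-index) for the fixed channel order.

    The order here is the contract shared with the compiled SSA kernel.
    """
    s2s = params.replication_topology == "singleton_to_singleton"
    rep_w = (1, 0, 0, 0) if s2s else (-1, 2, 0, 0)
    rep_m = (0, 0, 1, 0) if s2s else (0, 0, -1, 2)
    table = [
        ("fusion_WS+WS", (-2, 2, 0, 0)),
        ("fusion_WF+WS", (-1, 1, 0, 0)),
        ("fission_WF", (1, -1, 0, 0)),
        ("fusion_MS+MS", (0, 0, -2, 2)),
        ("fusion_MF+MS", (0, 0, -1, 1)),
        ("fission_MF", (0, 0, 1, -1)),
        ("replication_WS", rep_w),
        ("replication_WF", (0, 1, 0, 0)),
        ("mitophagy_WS", (-1, 0, 0, 0)),
        ("replication_MS", rep_m),
        ("replication_MF", (0, 0, 0, 1)),
        ("mitophagy_MS", (0, 0, -1, 0)),
        ("fusion_WF+MS", (0, 0, -1, 1)),
        ("fusion_MF+WS", (-1, 1, 0, 0)),
        ("fusion_WS+MS", (-1, 1, -1, 1)),
    ]
    if params.mu_f > 0:
        table.append(("degradation_WF", (0, -1, 0, 0)))
        table.append(("degradation_MF", (0, 0, 0, -1)))
    return table


def propensity_vector(x, params: ModelParams, deterministic: bool = False) -> np.ndarray:
    """Propensities of all channels, in the fixed channel order.

    ``deterministic=True`` replaces the integer-count pair combinatorics
    ``x*(x-1)/2`` by the large-n mass-action limit ``x**2/2`` (used by the
    mean-field ODE right-hand side).
    """
    ws, wf, ms, mf = (float(v) for v in _total(x))
    gw, gm = params.gamma_eff, params.gamma_mut
    beta = params.beta_eff
    lam = replication_rate((ws, wf, ms, mf), params)
    dw = degradation_rate((ws, wf, ms, mf), params, "W")
    dm = degradation_rate((ws, wf, ms, mf), params, "M")

    if deterministic:
        pair_w = ws * ws / 2.0
        pair_m = ms * ms / 2.0
    else:
        pair_w = ws * (ws - 1.0) / 2.0
        pair_m = ms * (ms - 1.0) / 2.0

    p = [
        gw * pair_w,
        gw * wf * ws,
        beta * wf,
        gm * pair_m,
        gm * mf * ms,
        beta * mf,
        lam * ws,
        lam * wf,
        dw * ws,
        lam * ms,
        lam * mf,
        dm * ms,
        gm * wf * ms,
        gm * mf * ws,
        gm * ws * ms,
    ]
    if params.mu_f > 0:
        p.append(params.mu_f * wf)
        p.append(params.mu_f * mf)
    return np.maximum(np.asarray(p, dtype=np.float64), 0.0)


def build_reaction_network(params: ModelParams) -> ReactionNetwork:
    """Enumerate the reaction channels for the two-genotype model.

    Returns exactly 15 channels (17 when ``mu_f > 0`` adds fused-species
    degradation).  Fusion channels involving at least one mutant molecule use
    the selective rate ``gamma/(1+eps_f)``.
    """
    table = _channel_table(params)

    def make_prop(i):
        def prop(state, p=params, i=i):
            return float(propensity_vector(state, p)[i])
        return prop

    reactions = tuple(
        Reaction(label=label, stoich=stoich, propensity=make_prop(i))
        for i, (label, stoich) in enumerate(table)
    )
    return ReactionNetwork(reactions=reactions)


def stoichiometry_matrix(params: ModelParams) -> np.ndarray:
    """Channels x species signed stoichiometry matrix (int64)."""
    return np.array([s for _, s in _channel_table(params)], dtype=np.int64)


def propensities(state, params: ModelParams, network: ReactionNetwork | None = None) -> np.ndarray:
    """Propensity vector for ``state`` (thin wrapper over the channel table)."""
    return propensity_vector(state, params)
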