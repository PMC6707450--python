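# mitonet

Coupled simulation of mitochondrial network dynamics (fusion–fission) and
mtDNA population genetics in single postmitotic cells.

## The problem

Cells carry hundreds to thousands of mtDNA copies, continuously replicated
and degraded ("relaxed replication"). The fraction of mutant copies per cell
— heteroplasmy, h — drifts stochastically, and its cell-to-cell **variance**
V(h) determines how many cells in a tissue cross a pathological threshold,
making it central to mitochondrial disease and aging. mtDNAs also live
inside a network of organelles that fuses and fragments, and only small
(unfused) fragments are susceptible to mitophagy. `mitonet` is for
quantitative biologists who want to explore how the *physical* network state
couples to the *genetic* dynamics of heteroplasmy.

Each mtDNA carries a genotype (wild type W / mutant M) and a network state
(singleton S / fused F). Fifteen reaction channels — fusion, fission,
replication, mitophagy, and genotype-crossing fusions — act on the state
(ws, wf, ms, mf), with copy number controlled through a linear replication
feedback λ = μ + b(κ − (wT + δ·mT)). The central law the package verifies
is that, starting from the deterministic steady state, heteroplasmy variance
grows linearly at a rate set by the **fraction of unfused mtDNAs** fs, not
by the absolute network rates:

    V(h) ≈ (2 μ fs / n) · h(1−h) · t

with μ the mitophagy rate and n the copy number. Fusion shields mtDNAs from
turnover and thereby rescales the drift clock. The same time-rescaling makes
de novo mutation accumulation (an infinite-sites Moran model with event rate
Γ = μ n fs) proportional to fs, and it vanishes when copy number is
controlled through degradation instead of replication. With selective fusion
(mutants excluded from the network at rate γ/(1+ε_f)), intermediate
fusion:fission ratios clear mutants best; with selective mitophagy
(μ(1+ε_m) for mutants), complete fragmentation is optimal.

## Worked example

```python
import numpy as np
from mitonet import (calibrate_replication_control, steady_state,
                     simulate_ensemble, variance_slope, normalized_theory_slope)

# nominal cell: n=1000 mtDNAs, half unfused, mu=0.023/day; network rates
# run at a tenth of the biological magnitude (the result is magnitude-free)
params = calibrate_replication_control(mu=0.023, n_target=1000,
                                       fs_target=0.5, M=0.1)
ss = steady_state(params, h_target=0.3)
print(f"steady state: n={ss.n_ss:.0f}, fs={ss.fs_ss:.2f}, "
      f"x0={np.rint(ss.state).astype(int)}")

rec = np.linspace(0, 1000, 21)                      # days
ens = simulate_ensemble(ss.initial_copy_state(), params,
                        1000, rec, n_traj=500, base_seed=1)
fit = variance_slope(ens)
print(f"theory  2*mu*fs/n = {normalized_theory_slope(ss, params):.3g} /day")
print(f"fitted  V(h)/(h0(1-h0)t) = {fit.slope_sim / (0.3 * 0.7):.3g} /day")
```

prints

```
steady state: n=1000, fs=0.50, x0=[350 350 150 150]
theory  2*mu*fs/n = 2.3e-05 /day
fitted  V(h)/(h0(1-h0)t) = 2.36e-05 /day
```

i.e. over 500 stochastic trajectories the normalized rate of variance
increase matches the closed-form prediction to ~2%: a cell turning over at
μ = 0.023/day with half its mtDNAs unfused accumulates heteroplasmy
variance at ≈ 2.3 × 10⁻⁵ · h(1−h) per day.

A CLI wraps the same machinery for config-driven runs
(`mitonet simulate|steady-state|variance-sweep|moran|qc-sweep --config FILE
--seed N --out DIR`); every run writes CSV outputs plus a `manifest.json`
that reproduces it bit-for-bit. See `docs/methods.md` for model details,
calibration, and numerical choices.

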