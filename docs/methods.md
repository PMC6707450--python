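# Methods

## The model

`mitonet` simulates the mitochondrial DNA (mtDNA) population of a single
postmitotic cell in which each molecule carries a genotype — wild type (W) or
mutant (M) — and a physical network state — singleton (S, in an unfused
mitochondrial fragment) or fused (F). The cell state is the copy-number
vector x = (ws, wf, ms, mf); heteroplasmy is h = (ms+mf)/n and the singleton
fraction is fs = (ws+ms)/n with n the total copy number.

The reaction system has three blocks per genotype pair:

* **Network processes** — pairwise fusion of singletons (S+S → F+F), fusion
  of a singleton onto a fused molecule (F+S → F+F), and fission (F → S),
  with stochastic rate constants γ (per molecule-pair per day) and β (per
  fused molecule per day). Fusion or fission events that create or remove no
  singleton (fused+fused fusion, internal fission of a fragment) change
  nothing in this representation and are omitted.
* **Genetic processes** — replication of singletons and of fused molecules
  at a common per-molecule rate λ, and mitophagy of singletons at rate μ.
  Only unfused molecules are degraded: autophagy of large network fragments
  is assumed negligible. Replication of a singleton yields two fused
  molecules by default (replication happens inside one organelle); the
  alternative topology in which singletons replicate into singletons is
  available and leaves the variance law unchanged.
* **Cross processes** — the three fusion channels pairing the genotypes.

That is 15 channels (6 network + 6 genetic + 3 cross); allowing a nonzero
degradation rate μ_f for fused species adds 2 more.

Copy number is controlled by a linear feedback in the replication rate,

    λ(x) = μ + b (κ − (wT + δ mT)),        clamped at 0,

where b is the control strength, κ the target-copy-number parameter, and δ
the mutant contribution to the sensed copy number ("maintenance of wild
type"; δ < 1 gives mutants a higher carrying capacity). The clamp is a
design decision: the linear law goes negative at large copy number and a
propensity must not. In the alternative **degradation-control** mode the
replication rate is a constant λ₀ and the feedback sits in the per-singleton
mitophagy rate, for which we adopt the mirror-image linear law
μ(x) = max(0, λ₀ + b(wT + δ mT − κ)). No canonical functional form exists
for this mode; the choice is validated by its qualitative property (loss of
network dependence, below), not by formula identity.

Selective quality control enters in two ways: selective fusion divides the
fusion rate by (1+ε_f) in every channel involving a mutant, and selective
mitophagy multiplies the mutant singleton degradation rate by (1+ε_m).

## Deterministic analysis and calibration

Mass-action ODEs (pair terms x(x−1) → x²) reduce, for the neutral model, to
a two-variable system in (n, fs) whose fixed points form a one-parameter
line indexed by heteroplasmy: turnover balance λ = μ fs, singleton-flux
balance γ n fs + (λ+μ) fs = β(1−fs), and the control line. The solver finds
fs by bracketed root-finding (Brent, tolerance 1e-14) after eliminating n
through the control line; every returned state must satisfy
|dx/dt| < 1e-8 · n. This reduction is exact under genotype symmetry, and is
verified against long-horizon integration (LSODA, rtol 1e-10).

The nominal operating point is a cell with n = 1000 mtDNAs, fs = 0.5,
mitophagy μ = 0.023/day, δ = 1, and network dynamics ~10³-fold faster than
turnover (β/μ = 1000). Because no standard table of (γ, β, b, κ) exists for
this operating point, the package calibrates: given targets (n, fs, μ, β/μ,
b) it solves γ and κ from the balance conditions in closed form
(`calibrate_replication_control`). The control strength defaults to
b = 1e-4 per molecule per day (copy-number relaxation time ~10 days at
n = 1000); the variance law is insensitive to this choice. The
degradation-control calibration uses λ₀ = 0.0115/day, matching the nominal
per-molecule turnover μ·fs of the replication-control cell.

## Stochastic simulation

Exact Gillespie direct-method sampling over the fixed channel ordering, with
full propensity recomputation per event (15–17 channels is small). The inner
loop is numba-compiled (~10⁷ events/s); the pure-Python reaction network is
the reference implementation and the two are pinned together by test.
Ensemble member i is seeded from `SeedSequence(base_seed)`, so runs are
bit-reproducible and order-independent. Trajectories are recorded on a fixed
grid with piecewise-constant semantics. A cell whose total propensity hits
zero is frozen (n = 0 is recorded as extinct); heteroplasmy is undefined at
n = 0, so extinct cells are excluded from E(h)/V(h) and reported separately.

**Network-rate magnitude.** The variance law is independent of the absolute
fission–fusion rate once it is much faster than turnover, so experiment
defaults run at magnitude M = 0.1 (β/μ ≈ 100) rather than the biologically
nominal M = 1, cutting event counts tenfold. The magnitude-independence
tests verify this is inconsequential (M = 0.1 vs 0.01 indistinguishable);
breakdown appears only near M ≈ 0.001, where network rates become comparable
to μ.

## The variance law and its error metric

In the quasi-stationary regime (fixation probability negligible),

    V(h) ≈ (2 μ fs / n) · h(1−h) · t     at the deterministic steady state,

and under degradation control V(h) ≈ (2 λ₀ / n) · h(1−h) · t with no
network dependence. Simulated slopes are fitted by least squares through the
origin (V(h,0) = 0 by construction) over record times whose fixation
fraction stays below 1%; agreement is summarized by
ε = |1 − V̇_theory / E_t(V̇_sim)| with V̇_sim estimated by finite differences
on the record grid. Experiments choose the horizon so the predicted
normalized variance reaches ~0.02–0.03, keeping the sublinearity bias from
incipient fixation at the percent level.

Ensemble sizes follow the sampling error of a variance: the relative error
of a fitted slope is ≈ √(2/N), so the sweep tests use N = 1000 trajectories
(≈4.5% noise) against a 0.15 acceptance band, and the reference experiment
uses N = 500 at n = 1000 over 1000 days.

## Infinite-sites Moran model

De novo mutation is modeled separately by a continuous-time Moran process
with fixed population n: events occur at rate Γ = μ n fs; at each event one
molecule is duplicated and one (possibly the same) removed, and the daughter
gains Q ~ Binomial(L, η) fresh mutations with L = 16569 bp and η = 5.6e-7
per base per doubling. Mutation identifiers are sequential integers
(infinite sites: every mutation unique, no back-mutation). Because fs enters
only through Γ, it rescales time exactly — with matched seeds, (fs, 2t) and
(2fs, t) give identical realizations — which the tests exploit. "Distinct
mutations per cell" counts all identifiers present in ≥1 molecule; a
segregating-only count (excluding mutations fixed in the cell) is also
reported, since either convention is defensible.

## Quality-control sweeps

The selective-clearance experiment varies the fusion rate over a logarithmic
grid of multipliers (10⁻²–10²) at fixed selectivity. Each grid point is
initialized on the *neutral* steady-state line at h₀ = 0.3 (so its copy
number follows the line as fs changes), selectivity is switched on, and mean
heteroplasmy is evaluated at 1000 days. The desk-scale protocol uses
n₀ = 200, 500 iterations per point, and selectivities ε_f = 4 or ε_m = 4;
the mechanism is strong enough that effect sizes (Δh ~ 0.1–0.3) dwarf the
Monte-Carlo error (~0.007). The grid argmin is reported with a boundary flag
and a 2-SE significance check against the grid endpoints.

## What the generator does and does not emulate

All data are generated by the model itself; there is no external input. The
simulator captures stochastic turnover, drift, feedback control, binary
network state, and selective QC, but not: spatial structure or discrete
organelles containing multiple mtDNAs (network state is a per-molecule
label), cell division and partitioning noise (a major variance source in
dividing tissues), de novo mutation within the network simulator (handled
by the separate Moran model with fs as a fixed scalar), or selection on
accumulated Moran mutations. Passing tests therefore validate the model's
internal laws, not their quantitative transfer to any particular tissue.

## Numerical choices and degenerate inputs

* Propensity combinatorics: same-genotype pair fusion uses γ x(x−1)/2,
  cross-genotype γ ws ms, fused+singleton γ f s (labeled-pair convention).
  The convention only rescales the effective fusion rate and is absorbed by
  the fs calibration.
* ODE integration rtol 1e-10 / atol 1e-8; steady-state residual tolerance
  1e-8·n; root finding xtol 1e-14.
* The γ→0 limit gives fs → 1 only up to O(μ/β) because replication feeds
  the fused pool; the β→0 limit (fs = 0, n = κ + μ/b) is exact.
* Empty cells: h and fs raise an undefined-state error at n = 0; the SSA
  records extinction instead of raising.
* Integer initialization: steady states are rounded to integer copy
  numbers; normalized slopes use the realized h₀ of the rounded state.

## Known limitations

The degradation-control law and the nominal (b, κ) pair are package choices
constrained only by steady-state targets; other monotone feedback forms
would alter transients but not the tested properties. The fitted-slope CI is
a percentile bootstrap over trajectories (200 resamples), which is adequate
for overlap checks but not for precise coverage. At very small copy numbers
(n ≲ 50) the diffusion-limit variance law degrades before the fixation
check triggers.
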