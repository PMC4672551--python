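# Methods

## Model

`ecomemory` simulates a community of `N` competing species with densities
`x_i ≥ 0` evolving on two separated timescales.

**Ecological (fast) timescale.** Densities follow generalised Lotka–Volterra
competition,

    dx_i/dt = (m_i x_i / k_i) · (k_i + Σ_j ω_ij x_j),

where `m_i > 0` is the intrinsic growth rate, `k_i > 0` the carrying
capacity of species `i` in the current environment, and `Ω = (ω_ij)` the
community matrix: the per-capita fitness effect of species `j` on `i`
relative to the self-effect, with `ω_ii = −1` fixed and all off-diagonal
entries competitive (`ω_ij < 0`). The sum includes `j = i`, so a lone
species is logistic with equilibrium `x* = k`. Growth is multiplicative in
`x_i`: a species at zero density stays there, and integration clamps
densities at exactly zero. We integrate by forward Euler with step `dt`
(default 1.0; one "iteration" of the dynamics). At the shipped parameters
the discrete-map eigenvalues stay well inside the unit circle while the
community is competitive, so no stiff solver is needed; a non-finite update
raises an error advising a smaller `dt`. Equilibration runs up to `τ` steps
with optional early stopping when the max-norm update falls below
`stop_tol` (default 1e-9; set 0 to always run the full budget).

**Evolutionary (slow) timescale.** Only individual-level selection acts.
A mutation in species `i` that weakens the incoming competition `ω_ij` by
`g` confers a per-capita invasion advantage `s = (m_i/k_i)·g·x_j`, so only
reductions of competitive magnitude are ever selected; changes to `ω_ji`
(effects on others) carry no individual benefit. Beneficial mutations
arise at rate `μ` per individual per generation; with supply `x_i μ` and
fixation probability `P(s)` the expected per-generation change of `ω_ij`
("rate of adaptation") is `v_ij = x_i μ P`. Three population-genetic
regimes for `P` are implemented (`β = m_i g / k_i`):

| model | formula | extra parameter |
|---|---|---|
| `serial` (no interference) | `v = β μ x_i x_j` | — |
| `linked_linear` (linked loci, linear genome) | `v = 2βμ x_i x_j / (1 + 4βμ x_i x_j / R)` | map length `R` (Morgans) |
| `facultative` (rare outcrossing) | `v = x_i μ s² (1 − 4 x_i μ s²/r²)`, `s = β x_j` | outcrossing rate `r` (valid while `r²/s² ≫ 4 x_i μ`; a warning fires below a safety factor of 10) |

All three vanish when `x_i x_j = 0` and increase with the density product:
co-occurring species "wire together", the unsupervised-correlation
(Hebbian) learning rule.

**Trade-offs.** Saturated niche space prevents selection from simply
eliminating competition: each species' total interaction budget is
conserved. After every selection update, alternating (Sinkhorn-style)
row/column rescaling restores `Σ_{j≠i} ω_ij = Σ_{j≠i} ω_ji = Q_i`
(`Q_i` = initial non-self row sum), leaving the diagonal untouched, until
the summed squared change between iterations drops below `norm_tol`
(default 1e-5) and the worst budget residual is within tolerance (floored
near machine precision). The matrix is then symmetrised (the studied
regime; a flag disables it). The net effect of selection-then-rescaling is
a signed, approximately Hebbian redistribution
`Δω ∝ (x − x̄)(x − x̄)ᵀ`: pairs jointly above or jointly below the mean
density compete less, mixed pairs more, pairs involving mean-density
species barely change.

**Generation loop.** Per generation: (1) the active environment sets
capacities `k_i = k0 + α ξ_i` from a ±1 pattern `ξ` (neutral environment
E0: all `k0`); (2) densities reset to `s0` and equilibrate; (3) the rate
model evaluated at the equilibrium proposes `Δω = update_gain · v`;
(4) rescaling and symmetrisation restore the budgets. Resetting densities
each generation makes generations exchangeable; state is carried across
steps only in the hysteresis sweep, where holding state is the point.

## Parameters

Full-scale defaults (`EvoConfig()` / `EvoConfig.paper_scale()`): `N=400`,
`m=0.5`, `s0=0.1`, `k0=10`, `α=0.1`, `T=1` (generations per environment),
`τ=5000`, `g=0.01`, `μ=1e-5`, `ω_offdiag(0)=−0.2`, `Q_i = −0.2(N−1)`,
800 generations. Desk scale (`EvoConfig.desk_scale()`, used by the test
suite and reproduction script): `N=100`, `τ=1500`, 300 generations, probe
budget `probe_tau=8000`.

**The update gain.** The absolute rate of adaptation is phenomenological:
only the *relative* rates across species pairs decide which interactions
strengthen or weaken, so the per-generation update carries a free scale
`update_gain`. We parameterise it through the effective Hebb step
`η = update_gain · (m g / k0) · μ` — the per-generation change of an
interaction per unit density product. With `update_gain = 1` (raw rates),
`η ≈ 5e-13` and no measurable reorganisation occurs on any feasible run
length; the presets therefore calibrate `η` against the memory threshold
below.

## Memory formation, its window, and calibration

Write the trained matrix as `Ω ≈ Ω0 + Σ_p D_p ξ_p ξ_pᵀ` (off-diagonal).
Linearising the dynamics around the uniform equilibrium
`x̄ = k0/(1 + |ω̄|(N−1))` shows a stored pattern becomes self-sustaining in
the neutral environment — an attractor — once

    D > D* = (1 + ω̄) / N        (ω̄ = −0.2 ⇒ D* = 0.8/N).

Monte-Carlo censuses of constructed matrices confirm the onset and reveal
an upper edge near `2 D*`: beyond it the *union* (mixture) of two stored
patterns becomes the dominant attractor and the pure pair disappears. The
two-pattern memory of interest therefore lives in a window
`D ∈ (D*, ~2D*)`. Because the forced response amplifies as `D → D*`
(forced amplitude `≈ α/(0.8 − ND)` until density clamping saturates it),
training accelerates super-linearly toward the threshold; run lengths and
`η` are chosen so each protocol *ends* in the regime it studies:

- `experiment1` (single pattern, `N=100`, `η=1.2e-3`, 300 generations)
  crosses `D*` near generation 140 and ends at `D ≈ 0.08`, deep in the
  (wide, single-pattern) stable regime.
- `experiment2` (two patterns, `N=200`, `η=6.3e-4`, 400 generations) ends
  at `D ≈ 0.005` against `D* = 0.004` — inside the two-attractor window.
- `longrun` continues to 480 generations: past `~2D*` the union state
  takes over (the census returns to one attractor) and far beyond that the
  positive feedback drives interactions toward zero and the dynamics
  destabilise, which is why the protocol stops at 480.

Two-pattern protocols use 200 species rather than the desk default 100:
the multiplicative rescaling couples stored patterns at order `1/N`, and
at `N=100` that cross-talk erodes the two-attractor window. They also use
*exactly orthogonal* balanced patterns: with correlated patterns the
union mode (eigenvalue `∝ 1+overlap`) is amplified fastest near onset and
self-reinforces, collapsing training straight into the mixture. Orthogonal
patterns additionally make every deterministic protocol quantity
seed-invariant, because the model is permutation-symmetric across species
and any two orthogonal balanced pairs are related by a relabeling.

## Measurement choices

- **Overlap score** between a state and a pattern:
  `(1/N) Σ_i sign(x_i − mean(x)) ξ_i`, with `sign(0) = +1`. It reads the
  community's composition pattern, not absolute densities.
- **Attractor census.** Initial densities uniform on `(0, 2x̄]`. Draws are
  kept only if closer to each stored pattern than to its complement
  (equivalently `x·ξ > 0` — complements of attractors are necessarily
  attractors in a correlation-encoded memory, and this half-space condition
  precludes them), with a retention margin of `filter_margin` (default
  0.5) standard deviations of the dot product, because draws essentially
  on the boundary commit to either side unpredictably. The basins
  interleave, so a rare filtered draw (~1% at `N=200`) still equilibrates
  onto a mirror-image state; such complement captures are likewise
  precluded from the census — identified conservatively as macroscopic
  (relative deviation amplitude ≥ 0.2) near-perfect sign anti-matches
  (overlap ≤ −0.9) of a stored pattern, so mixed or degraded attractors
  are never discarded — and reported in `n_complement_captured`.
  Equilibria are clustered at max-norm distance `cluster_tol` (1e-3).
  Probes and censuses
  use a deeper step budget (`probe_tau`) than training because relaxation
  slows critically near the memory threshold.
- **Probe states** never contain exact zeros (growth is multiplicative).
  `cue_init` puts a random fraction of species at pattern-consistent
  high/low densities (1.5/0.1 × `x̄`) over a uniform baseline;
  `corrupt_init` re-randomises a fraction of a pattern state;
  `mixture_init` assigns species to one of two pattern states, stratified
  over the agreeing/disagreeing species so the realised resemblance equals
  the nominal ratio (otherwise sampling noise is comparable to a 55:45
  imbalance). At a 50:50 ratio the seed is the documented tie-break.
  Because an 80%-corrupted state carries only a noisy 20% signal,
  single probes can legitimately fall into the other basin; repair and
  classification statistics are medians over independent replicates.
- **Hysteresis.** Forcing interpolates linearly between two patterns while
  the equilibrated state is carried from one forcing level to the next;
  the loop area is the trapezoid integral of |up − down| overlap over λ.
  In the trained community the transition between the two stored states
  passes through an intermediate, partially ordered branch, so each sweep
  shows a staircase: release of the start pattern near the midpoint, then
  a discontinuous commitment to the opposite pattern deep past it. The
  relaxation length (Euler steps to equilibrium) peaks immediately before
  the commitment jump — critical slowing down. The naive community shows
  a step response at the midpoint with coincident up/down curves, and the
  trained community responds gradedly (no loop) to forcing toward an
  arbitrary, untrained pattern.

## What the synthetic patterns do and do not emulate

Generated environments are balanced random (optionally fixed-overlap) ±1
patterns standing in for arbitrary field conditions; results are meant to
be pattern-robust, not pattern-exact. Real environmental states are not
balanced, uncorrelated, or binary, and real communities are neither
permutation-symmetric nor uniform in `m`, `k0` and initial interactions;
passing tests demonstrate the mechanism (selection + conserved budgets ⇒
correlation learning ⇒ associative memory), not a calibrated prediction
for any particular ecosystem.

## Numerical notes and limitations

- Forward Euler with `dt=1` is stable for the protocols shipped here;
  deep in the breakdown regime (interactions approaching zero or positive)
  the dynamics genuinely destabilise and the integrator reports blow-up.
- Rescaling assumes strictly negative off-diagonals; entries reaching zero
  or positive trigger warnings, and a vanishing off-diagonal row sum
  aborts with the row named.
- Early stopping (`stop_tol`) trades bit-level reproducibility of the full
  `τ`-step protocol for speed; `stop_tol=0` restores the fixed-length run.
- Asymmetric (e.g. trophic) interactions, mutualism, stochastic
  demography, explicit multilocus genetics and non-separated timescales
  are out of scope.
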