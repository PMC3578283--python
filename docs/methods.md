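# Methods

## Model and assumptions

The microscopic model is a fully connected network of `N` stochastic binary
neurons updated synchronously.  Neuron `i` fires at step `t+1` with
probability `g(h_i(t)) = (1 + tanh(h_i/T))/2`; `T > 0` is the noise
intensity (the package enforces `T ≥ 1e-6`; the deterministic `T → 0` limit
is exposed only as a sign-threshold helper for exploration).  Each synapse
carries two Tsodyks–Markram state variables: the releasable resource
`x ∈ [0,1]` (depleted by the factor `u` on firing, recovering to 1 with
time constant `tau_R ≥ 1` steps) and the utilization `u ∈ [U_se, 1]`
(incremented on firing, relaxing to the baseline release fraction
`U_se ∈ (0,1]` with time constant `tau_F ≥ 1`).  In the resource update the
product `s x u` uses the *pre-facilitation* `u(t)`; this ordering is what
makes the closed-form steady-state maps below exact fixed points of the
simulated dynamics.  Both bounds are preserved by the update for any
admissible parameters — this is tested over 10^5 iterations.

Memories are `p = 3` correlated patterns: a uniform random parent
`ξ ∈ {−1,1}^N` and children that copy each parent bit with probability
`(1+b)/2`.  The empirical parent–child direction cosine concentrates at `b`
and the child–child cosine at `b²`.  Couplings are Hebbian,
`J_ij = (1/N) Σ_μ ξ_i^μ ξ_j^μ` with `J_ii = 0`.  The coupling matrix is
never materialized: the field is evaluated through the rank-`p` identity
`J σ = (1/N) Σ_μ ξ^μ (ξ^μ·σ) − (p/N) σ`, O(Np) per step, and is tested
against a dense-matrix oracle at small `N`.

## Mean-field reduction

Averaging over the firing noise and dropping the O(1/N) correlations among
`(s_j, x_j, u_j)` gives a per-neuron deterministic map (the *microscopic*
mean field).  Since `J_ij = (η·η')/N` depends only on the pattern-bit tuples
of the two neurons, a state constant on each of the `2^p` sublattices
`I_η = {i : (ξ_i^1..ξ_i^p) = η}` stays constant on them, and the dynamics
closes exactly on the 24 variables `(m_η, X_η, U_η)`:

    m_η' = g( Σ_η' p_η' (η·η') (2 m_η' X_η' U_η' / U_se − 1) ),
    X_η' = X_η + (1−X_η)/tau_R − m_η X_η U_η,
    U_η' = U_η + (U_se−U_η)/tau_F + U_se (1−U_η) m_η.

Sublattice order is fixed (lexicographic, `(1,1,1)` first; index `2^p−1−k`
is always `−η_k`) across all state vectors and Jacobians.  Relative sizes
`p_η` default to the closed form `(1+3b²)/8` for `η = ±(1,1,1)` and
`(1−b²)/8` otherwise (the infinite-N values; all bifurcation analysis uses
these); empirical sizes from a concrete draw are used when comparing against
stochastic runs.  With empirical sizes *and* the `J_ii = 0` self-term
correction `h_η −= (p/N) σ_η` (the `finite_n` argument of `macro_mf_step`)
the reduction is exact: a sublattice-constant microscopic trajectory at
`N = 800` matches the macroscopic one to ~1e-14 over 10^3 steps, which is
the package's strongest internal consistency check.

At a steady state the synaptic variables are slaved to the activity:
`U(m) = U_se(1+tau_F m)/(1+tau_F U_se m)`, `X(m) = 1/(1+tau_R U(m) m)`.
Fixed points are therefore solved in the reduced 8-dimensional `m` system;
residuals are required below 1e-11 (max norm).

## Jacobian and stability

The analytic 24×24 Jacobian has full blocks in the activity rows — the
derivative of `m_η'` with respect to `m_η'`, `X_η'` and `U_η'` shares the
prefactor `g'(h_η) p_η' (η·η')` with remaining factors `2XU/U_se`,
`2mU/U_se` and `2mX/U_se` respectively — and diagonal blocks for the
synaptic rows; the utilization row has no resource dependence.  Every block
assignment is confirmed entrywise against a central-difference Jacobian
(step 1e-6) to better than 1e-9 at random admissible states in all three
parameter regions.  A fixed point is *stable* when the spectral
radius is below `1 − 1e-8`; points within the margin are flagged marginal.

## Continuation and bifurcation detection

Branches are continued in `T` by natural-parameter stepping (default
ΔT = 5e-3, adaptive halving, minimum 1e-6) with a per-step continuity bound
(max-norm 0.05 on `m`) and a class-label check.  Plain Newton on the reduced
system becomes singular exactly at transcritical crossings; the solver
therefore works in the subspace fixed by the stabilizer of the branch seed
under pattern permutations (all of S3 for the symmetric mixture, the swap of
the two non-distinguished patterns for memory and asymmetric-mixture
branches).  Crossings that break those symmetries are then transverse to the
Newton space, and continuation passes through them; an isolated singular
point inside the subspace is skipped by one extrapolated step.  Branch ends
are recorded as `fold` (step underflow; refined to 1e-6 in `T` by existence
bisection — Newton from an extrapolated seed succeeds below the fold and
fails or changes class above it), `merged` (the solution slid into another
class, e.g. a mixture branch coalescing with the paramagnetic trunk), or
`range-end`.

Unit-circle crossings of the Jacobian spectrum along a branch are bisected
in `T` to 1e-4 (refinement is monotone: halving the tolerance moves a
detected point by less than the previous tolerance).  Types:

* **NS** — a complex-conjugate pair crosses modulus 1.
* **PF** — a real crossing at a spin-flip-invariant state (`m ≡ 1/2`); the
  symmetric trunk sheds or absorbs a symmetry-related pair.
* **TC** vs **SN** for real crossings elsewhere — companion fixed points are
  probed near the critical point along the critical eigenvector at
  `T* ± 0.01`: companions present on both sides mean a transversally
  crossing branch (stability exchange, TC); companions on one side only mean
  a pair annihilating onto the branch, which is reported as a saddle-node
  collision (SN), the convention used in the literature this package
  follows; no companions found yields the honest label `real-crossing`.
  A fold at a branch end is always SN.

The spin flip `m → 1 − m` and pattern permutations are exact symmetries of
the map; every memory fixed point generates the full six-fold orbit
(3 patterns × 2 signs) of valid fixed points, and for every fixed point the
state `m'(η) = 1 − m(−η)` (with `X, U` re-slaved) is again a fixed point.
Both properties are asserted in the tests for every solution found.

## Brute-force attractor scans

Oscillatory attractors (quasi-periodic circles born at NS points) are mapped
by long orbit iteration: 5·10^3 transient steps, 10^4-step measurement
window, and an oscillation threshold of 1e-3 on the peak-to-peak overlap
amplitude.  Band endpoints in `T` are traced with step 1e-3 by *orbit
inheritance* (the previous attractor seeds the next parameter point), which
tracks a subcritical circle into its range of coexistence with stable fixed
points.  A caveat that matters for the subcritical (low-`T`) endpoints: they
are properties of the attractor's basin, not of the fixed-point spectrum.
Under orbit inheritance the in-phase circle of the facilitation-dominant
region remains an attractor well below the range in which random or
canonical initial conditions commonly reach it (its basin fraction decays
smoothly to ~0.5% with no sharp boundary), so the inherited-orbit endpoint
reported by this package is substantially lower than a random-restart scan
would suggest; the supercritical endpoints coincide with NS points of the
coexisting branch and are protocol-independent.  Orbits are classified by
the mean effective dimension (MED) of the overlap triple at tolerance
ε = 1e-5: OS1 (MED = 1, in-phase), OS2 (1 < MED ≤ 2, one dominant pattern),
OS3 (2 < MED ≤ 3, circulation among patterns).  For deterministic mean-field
fixed points the classification tolerances are 1e-6; time-averaged
stochastic traces use 0.05.

Phase diagrams evaluate each parameter cell independently: the canonical
15-seed family (paramagnetic, 6 memory, 2 symmetric-mixture, 6
asymmetric-mixture seeds, with `X, U` slaved) is solved and stability flags
per class recorded, and short orbits (2·10^3 transient, 4·10^3 window) from
the seed family plus a few random starts detect coexisting oscillations.
Boundary polylines are emitted as cell-edge midpoints where a flag flips.

## Stochastic model and validation

The stochastic simulator draws all `N` neurons independently per step from
`g(h_i)`; pattern generation and neuron updates use independently seeded RNG
streams so a pattern set is reproducible regardless of simulation length.
Runs are bit-reproducible given the seed.  Validation against the mean
field: at `N = 10^4`, time-averaged overlaps in the fixed-point regime match
mean-field fixed points within 0.05, and in the oscillatory regime the
(noise-broadened) orbit encloses the mean-field invariant circle to the same
tolerance.  Finite-size deviations scale like `1/sqrt(N p_η)` per step.

## Problem sizes and defaults

Headline parameters: `N = 10^4`, `p = 3`, `b = 0.2`, `U_se = 0.1`.  The
three synaptic regimes analyzed are `(tau_R, tau_F) = (4, 2)` (weak
plasticity), `(10, 2)` (depression-dominant) and `(4, 24)`
(facilitation-dominant).  The test suite uses `N ≤ 10^4` for stochastic runs
and `N = 800` for the exactness check, sizes at which the full suite runs in
well under a minute on one CPU; the long orbit scans are JIT-compiled when
numba is available, with an identical pure-numpy fallback.

## Known limitations

* The effective dimension, the closed-form sublattice sizes, and the state
  taxonomy are defined for `p = 3` only; other `p` are supported by the
  simulators and the generic map but classified only as raw overlap data.
* Mean-field accuracy rests on the independence of `(s, x, u)` at large
  `N`; with facilitation the `x`–`u` correlation does not vanish exactly,
  and the package validates the closure only empirically through the
  stochastic comparison.
* Continuation is single-parameter (in `T`); codimension-2 curves in phase
  diagrams are resolved by gridding, not by two-parameter continuation.
* Subcritical oscillation-band endpoints depend on the scan protocol (see
  above); only the orbit-inheritance convention is implemented as the
  reported number.
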