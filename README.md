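# dynamem

Associative memory networks with **dynamic synapses** — stochastic
simulation, an exact sublattice mean-field reduction, and a fixed-point
continuation / bifurcation toolkit.

Recurrent attractor networks store memory patterns in Hebbian couplings, but
real cortical synapses are not static: repeated presynaptic firing depletes
the releasable neurotransmitter pool (short-term depression, recovery time
`tau_R`) and raises the release probability (short-term facilitation, decay
time `tau_F`).  `dynamem` is for computational neuroscientists who want to
know what these two time scales do to memory retrieval: where retrieval
states exist and are stable, where they give way to spurious mixtures, and
where depression turns fixed-point attractors into oscillations that visit
the stored patterns in sequence.

## Model

`N` binary neurons `s_i ∈ {0,1}` update synchronously with firing
probability

    Prob[s_i(t+1) = 1] = g(h_i(t)),     g(h) = (1 + tanh(h/T)) / 2,

where `T` is the noise intensity.  The recurrent field weighs each
presynaptic signal by the instantaneous synaptic efficacy `x_j u_j`:

    h_i = Σ_{j≠i} J_ij (2 s_j x_j u_j / U_se − 1),
    x_j(t+1) = x_j + (1 − x_j)/tau_R − s_j x_j u_j,
    u_j(t+1) = u_j + (U_se − u_j)/tau_F + U_se (1 − u_j) s_j.

Couplings are Hebbian over `p = 3` child patterns `ξ^μ ∈ {−1,1}^N` drawn
around a common parent with correlation level `b`
(`J_ij = (1/N) Σ_μ ξ_i^μ ξ_j^μ`, `J_ii = 0`).  Because `J_ij` depends only
on the two neurons' pattern-bit tuples, the noise-averaged dynamics closes
exactly on the `2^p` *sublattices* (groups of neurons sharing the same bits),
giving a deterministic `3·2^p = 24`-dimensional map for the sublattice means
`(m_η, X_η, U_η)`.  Retrieval quality is tracked by the overlaps
`M^μ = Σ_η p_η η^μ (2 m_η − 1)`.

On top of the map the package provides the analytic Jacobian, Newton
continuation of fixed-point branches in `T` (symmetry-reduced, so
transcritical crossings do not stall the solver), detection and typing of
saddle-node / Neimark–Sacker / transcritical / pitchfork bifurcations,
brute-force attractor scans, and classification of states (MEM, SMIX, AMIX,
PARA fixed points; OS1/OS2/OS3 oscillations via the effective dimension of
the overlap orbit).

## Worked example

`examples/bifurcation_diagram.py` continues the four fixed-point families in
the noise intensity for weakly dynamic synapses (`tau_R = 4`, `tau_F = 2`,
`U_se = 0.1`, `b = 0.2`) and prints:

```
AMIX+1: 99 points, ends by 'fold'
   SN  at T = 0.4299   (lambda = 1.0003+0.0000j)
   SN  at T = 0.5194   (lambda = 0.9982+0.0000j)
SMIX+: 289 points, ends by 'merged'
   TC  at T = 0.7810   (lambda = 1.0000+0.0000j)
   TC  at T = 1.1609   (lambda = 1.0000+0.0000j)
MEM+1: 246 points, ends by 'fold'
   SN  at T = 1.2475   (lambda = 1.0002+0.0000j)
PARA: 61 points, ends by 'range-end'
   PF  at T = 1.4880   (lambda = 1.0000+0.0000j)
```

Reading: at low noise the memory states (MEM) coexist with symmetric (SMIX)
and asymmetric (AMIX) mixtures.  Raising `T` first destabilizes the
asymmetric mixtures (saddle-node collision at `T ≈ 0.430`), the symmetric
mixtures exchange stability twice with crossing branches (`T ≈ 0.781`,
`1.161`), the six memory states fold away at `T ≈ 1.248`, and at
`T ≈ 1.488` the mixtures merge with the trunk in a pitchfork, leaving the
zero-overlap paramagnetic state as the unique attractor.  The other example
scripts show stochastic-vs-mean-field retrieval (`retrieve_memory.py`), the
fixed-point landscape (`fixed_point_landscape.py`), depression-induced
quasi-periodic oscillations and their OS1/OS2/OS3 classification
(`oscillatory_states.py`), and a coarse brute-force phase diagram
(`phase_diagram_small.py`).

A thin CLI wraps the same calls: `dynamem simulate|meanfield|fixedpoints|
continue|bifurcations|phase|classify` (see `dynamem --help`).

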