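"""Microscopic stochastic network of binary neurons with dynamic synapses.

Fully synchronous update: from the state (s, x, u) at step t, the field

    h_i = sum_{j != i} J_ij (2 s_j x_j u_j / U_se - 1)

drives independent Bernoulli draws s_i(t+1) ~ g(h_i), while the synaptic
variables advance deterministically,

    x_j(t+1) = x_j + (1 - x_j)/tau_R - s_j x_j u_j,
    u_j(t+1) = u_j + (U_se - u_j)/tau_F + U_se (1 - u_j) s_j,

with u_j on the right-hand side taken at step t (pre-facilitation).  These
updates keep x in [0, 1] and u in [U_se, 1] whenever tau_R, tau_F >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams, response_function, response_derivative  # noqa: F401
from .patterns import MemoryPatternSet, build_sublattices, synaptic_field

__all__ = [
    "NetworkState",
    "OverlapTrace",
    "response_function",
    "deterministic_response",
    "effective_signal",
    "step",
    "simulate",
    "overlap",
    "initial_state",
    "save_trace_csv",
]


@dataclass
class NetworkState:
    """Per-neuron activity s in {0,1}, resource x in [0,1], utilization u."""

    s: np.ndarray
    x: np.ndarray
    u: np.ndarray
    t: int = 0

    def validate(self, params: ModelParams) -> None:
        if not np.isin(self.s, (0, 1)).all():
            raise ValueError("s entries must be 0 or 1")
        if (self.x < -1e-12).any() or (self.x > 1 + 1e-12).any():
            raise ValueError("x entries must lie in [0, 1]")
        if (self.u < params.U_se - 1e-12).any() or (self.u > 1 + 1e-12).any():
            raise ValueError("u entries must lie in [U_se, 1]")


@dataclass
class OverlapTrace:
    """Per-step overlaps M^mu(t) between network activity and each memory."""

    times: np.ndarray  # (n_steps,)
    M: np.ndarray  # (n_steps, p), entries in [-1, 1]


def deterministic_response(h: np.ndarray) -> np.ndarray:
    """T -> 0 limit of the response: a hard threshold at h = 0.

    Returns 1 for h > 0, 0 for h < 0 and 1/2 at h = 0 (the limit of the
    sigmoid).  Exploratory helper; the simulator itself requires T > 0.
    """
    return np.where(h > 0, 1.0, np.where(h < 0, 0.0, 0.5))


def effective_signal(state: NetworkState, params: ModelParams) -> np.ndarray:
    """Presynaptic drive 2 s x u / U_se - 1 entering the field."""
    return 2.0 * state.s * state.x * state.u / params.U_se - 1.0


def step(
    state: NetworkState,
    patterns: MemoryPatternSet,
    params: ModelParams,
    rng: np.random.Generator,
) -> NetworkState:
    """One synchronous update of all neurons and synapses."""
    h = synaptic_field(patterns, effective_signal(state, params))
    prob = response_function(h, params.T)
    s_new = (rng.random(patterns.N) < prob).astype(np.int8)
    x_new = state.x + (1.0 - state.x) / params.tau_R - state.s * state.x * state.u
    u_new = state.u + (params.U_se - state.u) / params.tau_F + params.U_se * (1.0 - state.u) * state.s
    return NetworkState(s=s_new, x=x_new, u=u_new, t=state.t + 1)


def overlap(s: np.ndarray, pattern: np.ndarray) -> float:
    """Overlap M = (1/N) sum_i xi_i (2 s_i - 1) in [-1, 1].

    Equals 1 iff the +-1 coded activity matches the pattern exactly and -1
    for the inverted pattern.
    """
    s = np.asarray(s)
    pattern = np.asarray(pattern)
    if s.shape != pattern.shape:
        raise ValueError(f"length mismatch: s has shape {s.shape}, pattern {pattern.shape}")
    return float(pattern @ (2.0 * s - 1.0)) / s.size


def initial_state(
    patterns: MemoryPatternSet,
    params: ModelParams,
    rng: np.random.Generator,
    init: str = "random",
) -> NetworkState:
    """Standard initial condition: x = 1, u = U_se, s per the chosen policy.

    ``init`` is "random" (each s_i Bernoulli(1/2), so all overlaps are
    O(1/sqrt(N))), "pattern:<mu>" (s encodes child pattern mu, 0-based) or
    "antipattern:<mu>" (its inversion).
    """
    N = patterns.N
    if init == "random":
        s = (rng.random(N) < 0.5).astype(np.int8)
    elif init.startswith(("pattern:", "antipattern:")):
        kind, mu_str = init.split(":", 1)
        mu = int(mu_str)
        if not 0 <= mu < patterns.p:
            raise ValueError(f"pattern index {mu} out of range for p={patterns.p}")
        sign = 1 if kind == "pattern" else -1
        s = ((sign * patterns.children[mu] + 1) // 2).astype(np.int8)
    else:
        raise ValueError(f"unknown init policy {init!r}")
    return NetworkState(s=s, x=np.ones(N), u=np.full(N, params.U_se), t=0)


def simulate(
    patterns: MemoryPatternSet,
    params: ModelParams,
    n_steps: int,
    init: str | NetworkState = "random",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    raster_neurons: Optional[Sequence[int] | int] = None,
) -> tuple[OverlapTrace, Optional[pd.DataFrame]]:
    """Iterate the stochastic network, recording overlaps each step.

    Overlaps are recorded for steps 0 .. n_steps (including the initial
    state).  If ``raster_neurons`` is given, active (t, neuron) pairs are
    collected for that subset; an integer n selects the first n neurons
    after sorting by sublattice label, mirroring how raster figures group
    neurons with identical stored bits.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = init if isinstance(init, NetworkState) else initial_state(patterns, params, rng, init)

    raster_idx = None
    if raster_neurons is not None:
        if np.isscalar(raster_neurons):
            order = np.argsort(build_sublattices(patterns).membership, kind="stable")
            raster_idx = order[: int(raster_neurons)]
        else:
            raster_idx = np.asarray(raster_neurons)

    xi = patterns.children
    M = np.empty((n_steps + 1, patterns.p))
    raster_rows: list[tuple[int, int]] = []

    def record(st: NetworkState, row: int) -> None:
        M[row] = xi @ (2.0 * st.s - 1.0) / patterns.N
        if raster_idx is not None:
            for j in raster_idx[st.s[raster_idx] == 1]:
                raster_rows.append((st.t, int(j)))

    record(state, 0)
    for k in range(1, n_steps + 1):
        state = step(state, patterns, params, rng)
        record(state, k)

    trace = OverlapTrace(times=np.arange(n_steps + 1), M=M)
    raster = (
        pd.DataFrame(raster_rows, columns=["t", "neuron"]) if raster_idx is not None else None
    )
    return trace, raster


def save_trace_csv(trace: OverlapTrace, path: str | Path) -> None:
    """Columns t, M1 .. Mp."""
    p = trace.M.shape[1]
    df = pd.DataFrame({"t": trace.times} | {f"M{mu + 1}": trace.M[:, mu] for mu in range(p)})
    df.to_csv(path, index=False)
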