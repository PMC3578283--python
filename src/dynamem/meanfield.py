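"""Mean-field reductions of the stochastic associative memory network.

Averaging the stochastic update over noise realizations (and assuming the
activity/resource/utilization correlations vanish at large N) yields the
*microscopic* mean-field map on per-neuron means (m_i, X_i, U_i).  Because
the Hebbian coupling between two neurons depends only on their sublattice
labels, J_ij = (eta . eta') / N, a state that is constant on each sublattice
stays so, and the dynamics closes exactly on the 3 * 2^p macroscopic
variables (m_eta, X_eta, U_eta):

    m_eta'  = g( sum_eta' p_eta' (eta.eta') (2 m_eta' X_eta' U_eta' / U_se - 1) )
    X_eta'  = X_eta + (1 - X_eta)/tau_R - m_eta X_eta U_eta
    U_eta'  = U_eta + (U_se - U_eta)/tau_F + U_se (1 - U_eta) m_eta

At a steady state the synaptic variables are slaved to the activity:

    U(m) = U_se (1 + tau_F m) / (1 + tau_F U_se m),
    X(m) = 1 / (1 + tau_R U(m) m).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .params import ModelParams, response_function
from .patterns import MemoryPatternSet, SublatticeSpec, synaptic_field

__all__ = [
    "SublatticeState",
    "SublatticeTrajectory",
    "steady_state_maps",
    "macro_field",
    "macro_mf_step",
    "macro_mf_simulate",
    "overlaps_from_sublattices",
    "micro_mf_step",
    "inversion_partner",
    "permute_state",
    "save_trajectory_csv",
]


@dataclass
class SublatticeState:
    """Mean activity m, resource X, utilization U on each of the 2^p sublattices.

    Vectors follow the fixed sublattice order of
    :func:`dynamem.patterns.sublattice_labels`.
    """

    m: np.ndarray
    X: np.ndarray
    U: np.ndarray

    def copy(self) -> "SublatticeState":
        return SublatticeState(self.m.copy(), self.X.copy(), self.U.copy())

    def as_vector(self) -> np.ndarray:
        """Concatenated (m, X, U), the 3*2^p-dimensional map state."""
        return np.concatenate([self.m, self.X, self.U])

    @classmethod
    def from_vector(cls, z: np.ndarray) -> "SublatticeState":
        n = z.size // 3
        return cls(z[:n].copy(), z[n : 2 * n].copy(), z[2 * n :].copy())

    @classmethod
    def from_activity(cls, m: np.ndarray, params: ModelParams) -> "SublatticeState":
        """State with X, U slaved to m via the steady-state maps."""
        m = np.asarray(m, dtype=float)
        X, U = steady_state_maps(m, params)
        return cls(m=m, X=X, U=U)

    @classmethod
    def rest(cls, spec: SublatticeSpec, params: ModelParams, m: float = 0.0) -> "SublatticeState":
        """Uniform activity m with fully recovered synapses (X=1, U=U_se)."""
        n = spec.n_sublattices
        return cls(np.full(n, float(m)), np.ones(n), np.full(n, params.U_se))

    def validate(self, params: ModelParams) -> None:
        if (self.m < -1e-12).any() or (self.m > 1 + 1e-12).any():
            raise ValueError("m entries must lie in [0, 1]")
        if (self.X < -1e-12).any() or (self.X > 1 + 1e-12).any():
            raise ValueError("X entries must lie in [0, 1]")
        if (self.U < params.U_se - 1e-12).any() or (self.U > 1 + 1e-12).any():
            raise ValueError("U entries must lie in [U_se, 1]")


@dataclass
class SublatticeTrajectory:
    """Time course of the macroscopic map with per-step overlaps."""

    times: np.ndarray
    m: np.ndarray  # (n_steps+1, 2^p)
    X: np.ndarray
    U: np.ndarray
    M: np.ndarray  # (n_steps+1, p) overlaps

    def final_state(self) -> SublatticeState:
        return SublatticeState(self.m[-1].copy(), self.X[-1].copy(), self.U[-1].copy())


def steady_state_maps(m, params: ModelParams):
    """Steady-state resource X(m) and utilization U(m) at constant activity m.

    U rises with m toward 1 (facilitation saturates), X falls with m
    (depletion); at m = 0 they rest at X = 1, U = U_se.
    """
    m = np.asarray(m, dtype=float)
    U = params.U_se * (1.0 + params.tau_F * m) / (1.0 + params.tau_F * params.U_se * m)
    X = 1.0 / (1.0 + params.tau_R * U * m)
    return X, U


def macro_field(state: SublatticeState, spec: SublatticeSpec, params: ModelParams,
                finite_n: Optional[int] = None) -> np.ndarray:
    """Sublattice fields h_eta = sum_eta' p_eta' (eta.eta') sigma_eta'.

    With ``finite_n`` = N, the J_ii = 0 self-term correction -(p/N) sigma_eta
    is included, making the map the exact image of the N-neuron microscopic
    mean field on sublattice-constant states.  The default (None) is the
    infinite-N map used for all bifurcation analysis.
    """
    sigma = 2.0 * state.m * state.X * state.U / params.U_se - 1.0
    h = spec.dot_matrix @ (spec.sizes * sigma)
    if finite_n is not None:
        h = h - (spec.p / finite_n) * sigma
    return h


def macro_mf_step(state: SublatticeState, spec: SublatticeSpec, params: ModelParams,
                  finite_n: Optional[int] = None) -> SublatticeState:
    """One step of the macroscopic 3*2^p-dimensional map."""
    h = macro_field(state, spec, params, finite_n)
    m_new = response_function(h, params.T)
    X_new = state.X + (1.0 - state.X) / params.tau_R - state.m * state.X * state.U
    U_new = state.U + (params.U_se - state.U) / params.tau_F + params.U_se * (1.0 - state.U) * state.m
    return SublatticeState(m=m_new, X=X_new, U=U_new)


def macro_mf_simulate(state0: SublatticeState, spec: SublatticeSpec, params: ModelParams,
                      n_steps: int, finite_n: Optional[int] = None) -> SublatticeTrajectory:
    """Iterate the macroscopic map (deterministic), recording overlaps."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n = spec.n_sublattices
    m = np.empty((n_steps + 1, n))
    X = np.empty_like(m)
    U = np.empty_like(m)
    M = np.empty((n_steps + 1, spec.p))
    state = state0.copy()
    for k in range(n_steps + 1):
        m[k], X[k], U[k] = state.m, state.X, state.U
        M[k] = overlaps_from_sublattices(state, spec)
        if k < n_steps:
            state = macro_mf_step(state, spec, params, finite_n)
    return SublatticeTrajectory(times=np.arange(n_steps + 1), m=m, X=X, U=U, M=M)


def overlaps_from_sublattices(state: SublatticeState, spec: SublatticeSpec) -> np.ndarray:
    """Overlaps M^mu = sum_eta p_eta eta^mu (2 m_eta - 1).

    On a sublattice-constant microscopic state this equals the microscopic
    overlap (1/N) sum_i xi_i^mu (2 s_i - 1) exactly (with empirical sizes).
    """
    return spec.labels.T @ (spec.sizes * (2.0 * state.m - 1.0))


def micro_mf_step(m: np.ndarray, X: np.ndarray, U: np.ndarray,
                  patterns: MemoryPatternSet, params: ModelParams):
    """One step of the N-neuron microscopic mean-field map (validation bridge).

    Same structure as the stochastic update with noise averages in place of
    samples; shares the O(Np) field evaluation (J_ii = 0 included).
    """
    sigma = 2.0 * m * X * U / params.U_se - 1.0
    h = synaptic_field(patterns, sigma)
    m_new = response_function(h, params.T)
    X_new = X + (1.0 - X) / params.tau_R - m * X * U
    U_new = U + (params.U_se - U) / params.tau_F + params.U_se * (1.0 - U) * m
    return m_new, X_new, U_new


def inversion_partner(state: SublatticeState, spec: SublatticeSpec,
                      params: ModelParams) -> SublatticeState:
    """Image of a state under the global spin-flip symmetry.

    The map commutes with m(eta) -> 1 - m(-eta) on fixed points: for every
    fixed point the partner with activity m'(eta) = 1 - m(-eta) (and X, U
    re-slaved through the steady-state maps) is also a fixed point, with all
    overlaps negated.
    """
    inv = spec.inversion_index()
    return SublatticeState.from_activity(1.0 - state.m[inv], params)


def permute_state(state: SublatticeState, spec: SublatticeSpec,
                  perm: tuple[int, ...]) -> SublatticeState:
    """Relabel the p memory patterns; sublattice vectors permute covariantly."""
    idx = spec.permutation_index(perm)
    out = state.copy()
    out.m[idx], out.X[idx], out.U[idx] = state.m, state.X, state.U
    return out


def save_trajectory_csv(traj: SublatticeTrajectory, path: str | Path) -> None:
    """Columns t, m_0..m_{2^p-1}, X_*, U_*, M1..Mp (sublattices in label order)."""
    n = traj.m.shape[1]
    p = traj.M.shape[1]
    cols: dict[str, np.ndarray] = {"t": traj.times}
    for tag, arr in (("m", traj.m), ("X", traj.X), ("U", traj.U)):
        for k in range(n):
            cols[f"{tag}_{k}"] = arr[:, k]
    for mu in range(p):
        cols[f"M{mu + 1}"] = traj.M[:, mu]
    pd.DataFrame(cols).to_csv(path, index=False)
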