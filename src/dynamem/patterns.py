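"""Correlated memory patterns, Hebbian couplings, and the sublattice partition.

Stored memories are p "child" patterns over {-1, +1}^N drawn around a common
random "parent": each child entry equals the parent entry with probability
(1 + b)/2.  The direction cosine between a child and the parent concentrates
at b, and between two children at b^2.  Couplings follow the Hebbian rule
J_ij = (1/N) sum_mu xi_i^mu xi_j^mu with J_ii = 0.

Neurons sharing the same p-tuple of pattern bits form a *sublattice*; the
2^p sublattices are the exact coarse-graining on which the macroscopic
mean-field model lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MemoryPatternSet",
    "SublatticeSpec",
    "generate_patterns",
    "build_sublattices",
    "expected_sublattice_sizes",
    "sublattice_labels",
    "synaptic_field",
    "dense_coupling_matrix",
    "save_patterns_csv",
    "load_patterns_csv",
]

# refuse to materialize the N x N coupling matrix above this size
_DENSE_LIMIT = 2000


def sublattice_labels(p: int) -> np.ndarray:
    """The 2^p sublattice label vectors eta in {-1, +1}^p, in fixed order.

    Ordering is lexicographic with +1 sorting first, so for p = 3:
    (1,1,1), (1,1,-1), (1,-1,1), (1,-1,-1), (-1,1,1), ..., (-1,-1,-1).
    Index ``2^p - 1 - k`` always holds ``-eta_k``; every module in this
    package uses this order for state vectors and Jacobians.
    """
    k = np.arange(2**p)[:, None]
    mu = np.arange(p)[None, :]
    return (1 - 2 * ((k >> (p - 1 - mu)) & 1)).astype(np.int64)


@dataclass(frozen=True)
class MemoryPatternSet:
    """Parent and child +-1 patterns with correlation level b."""

    N: int
    p: int
    b: float
    parent: np.ndarray  # shape (N,), entries +-1
    children: np.ndarray  # shape (p, N), entries +-1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        parent = np.asarray(self.parent)
        children = np.asarray(self.children)
        if parent.shape != (self.N,) or children.shape != (self.p, self.N):
            raise ValueError("pattern arrays do not match the declared (N, p)")
        for arr, name in ((parent, "parent"), (children, "children")):
            if not np.isin(arr, (-1, 1)).all():
                raise ValueError(f"{name} entries must be exactly -1 or +1")

    def direction_cosines(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical cos(theta_0) per child (vs parent) and cos(theta) per pair.

        Returns the length-p vector (1/N) sum_i xi_i xi_i^mu, expected ~ b,
        and the p(p-1)/2 pairwise values expected ~ b^2.
        """
        cos0 = self.children @ self.parent / self.N
        pairs = [
            self.children[mu] @ self.children[nu] / self.N
            for mu in range(self.p)
            for nu in range(mu + 1, self.p)
        ]
        return cos0, np.array(pairs)


@dataclass(frozen=True)
class SublatticeSpec:
    """Partition of neurons into the 2^p sublattices, with relative sizes.

    ``membership`` is None for the idealized (infinite-N) spec, where sizes
    come from the closed form rather than from a concrete pattern draw.
    """

    p: int
    labels: np.ndarray  # (2^p, p) eta vectors, fixed order
    sizes: np.ndarray  # (2^p,) relative sizes p_eta, sum to 1
    membership: Optional[np.ndarray] = None  # (N,) sublattice index per neuron

    def __post_init__(self) -> None:
        if self.labels.shape != (2**self.p, self.p):
            raise ValueError("labels must be the 2^p x p sublattice matrix")
        if not np.isclose(self.sizes.sum(), 1.0, atol=1e-12):
            raise ValueError("relative sublattice sizes must sum to 1")
        if (self.sizes < -1e-15).any():
            raise ValueError("relative sublattice sizes must be nonnegative")

    @property
    def n_sublattices(self) -> int:
        return 2**self.p

    @property
    def dot_matrix(self) -> np.ndarray:
        """Gram matrix eta . eta' of the label vectors (entries in [-p, p])."""
        return self.labels @ self.labels.T

    def inversion_index(self) -> np.ndarray:
        """Index array mapping each sublattice eta to -eta (a reversal)."""
        return np.arange(self.n_sublattices)[::-1].copy()

    def permutation_index(self, perm: tuple[int, ...]) -> np.ndarray:
        """Sublattice index array induced by relabeling the p patterns.

        ``perm[mu]`` is the new position of pattern mu.  Returns ``idx`` such
        that a sublattice-indexed vector v transforms as ``v[idx]``.
        """
        permuted = self.labels[:, list(perm)]
        # locate each permuted row in the canonical order
        weights = 1 << np.arange(self.p - 1, -1, -1)
        key = ((1 - permuted) // 2) @ weights
        return np.asarray(key)

    @classmethod
    def ideal(cls, b: float, p: int = 3) -> "SublatticeSpec":
        """Infinite-N spec with closed-form sizes (p = 3 only)."""
        return cls(p=p, labels=sublattice_labels(p), sizes=expected_sublattice_sizes(b, p))


def generate_patterns(N: int, p: int, b: float, seed: Optional[int] = None) -> MemoryPatternSet:
    """Draw a parent pattern and p correlated children.

    Parent entries are i.i.d. uniform on {-1, +1}; each child entry equals
    the parent entry with probability (1 + b)/2 and its negation otherwise.
    Reproducible given ``seed``.
    """
    if not 0 <= b <= 1:
        raise ValueError(f"correlation level b must lie in [0, 1], got {b}")
    if N < 1 or p < 1:
        raise ValueError("N and p must be positive")
    rng = np.random.default_rng(seed)
    parent = rng.choice(np.array([-1, 1], dtype=np.int64), size=N)
    agree = rng.random((p, N)) < (1 + b) / 2
    children = np.where(agree, parent[None, :], -parent[None, :])
    return MemoryPatternSet(N=N, p=p, b=b, parent=parent, children=children, seed=seed)


def build_sublattices(patterns: MemoryPatternSet) -> SublatticeSpec:
    """Partition neurons by their p-tuple of pattern bits; empirical sizes."""
    labels = sublattice_labels(patterns.p)
    weights = 1 << np.arange(patterns.p - 1, -1, -1)
    membership = ((1 - patterns.children.T) // 2) @ weights
    sizes = np.bincount(membership, minlength=2**patterns.p) / patterns.N
    return SublatticeSpec(p=patterns.p, labels=labels, sizes=sizes, membership=membership)


def expected_sublattice_sizes(b: float, p: int = 3) -> np.ndarray:
    """Closed-form relative sublattice sizes for p = 3 correlated patterns.

    (1 + 3 b^2)/8 for eta = +-(1,1,1), (1 - b^2)/8 for the other six.
    """
    if p != 3:
        raise NotImplementedError(
            "closed-form sublattice sizes are only available for p = 3; "
            "use build_sublattices on a concrete pattern draw for other p"
        )
    sizes = np.full(8, (1 - b * b) / 8.0)
    sizes[0] = sizes[7] = (1 + 3 * b * b) / 8.0
    return sizes


def synaptic_field(patterns: MemoryPatternSet, effective_signal: np.ndarray) -> np.ndarray:
    """Field h_i = sum_{j != i} J_ij sigma_j for a given effective signal sigma.

    Uses the rank-p identity J sigma = (1/N) sum_mu xi^mu (xi^mu . sigma)
    minus the self term (p/N) sigma, so the N x N coupling matrix is never
    materialized: O(N p) per call.
    """
    sigma = np.asarray(effective_signal, dtype=float)
    if sigma.shape != (patterns.N,):
        raise ValueError(f"effective signal must have length N={patterns.N}, got shape {sigma.shape}")
    xi = patterns.children.astype(float)
    return (xi.T @ (xi @ sigma) - patterns.p * sigma) / patterns.N


def dense_coupling_matrix(patterns: MemoryPatternSet) -> np.ndarray:
    """Explicit Hebbian matrix J (zero diagonal); small N only, for oracles."""
    if patterns.N > _DENSE_LIMIT:
        raise ValueError(f"refusing to build a dense {patterns.N}x{patterns.N} coupling matrix")
    xi = patterns.children.astype(float)
    J = xi.T @ xi / patterns.N
    np.fill_diagonal(J, 0.0)
    return J


def save_patterns_csv(patterns: MemoryPatternSet, path: str | Path) -> None:
    """One row per neuron: parent, child_1 .. child_p (values +-1)."""
    cols = {"parent": patterns.parent}
    for mu in range(patterns.p):
        cols[f"child_{mu + 1}"] = patterns.children[mu]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_patterns_csv(path: str | Path, b: float, seed: Optional[int] = None) -> MemoryPatternSet:
    """Inverse of :func:`save_patterns_csv`; b is metadata, not re-estimated."""
    df = pd.read_csv(path)
    child_cols = sorted(
        (c for c in df.columns if c.startswith("child_")),
        key=lambda c: int(c.split("_")[1]),
    )
    children = df[child_cols].to_numpy().T
    return MemoryPatternSet(
        N=len(df), p=len(child_cols), b=b,
        parent=df["parent"].to_numpy(), children=children, seed=seed,
    )
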