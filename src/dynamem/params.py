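"""Model parameters and the stochastic neuron's response function.

The network couples N binary neurons through Hebbian synapses whose
transmission efficacy varies with recent presynaptic activity: a releasable
resource x (recovering to 1 with time constant ``tau_R``, depression) and a
utilization fraction u (relaxing to ``U_se`` with time constant ``tau_F``,
facilitation).  The single neuron fires with probability
``g(h) = (1 + tanh(h/T)) / 2`` where ``T`` is the noise intensity (inverse
gain); ``T -> 0`` is the deterministic limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: smallest admissible noise intensity; below this the sigmoid degenerates
#: numerically.  Use :func:`dynamem.stochastic_net.deterministic_response`
#: to explore the T -> 0 limit.
MIN_T = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the stochastic network and its mean-field reduction.

    Attributes
    ----------
    T:
        Noise intensity 1/beta (dimensionless).  Larger T means noisier
        neuron updates.
    tau_R:
        Recovery time constant of the releasable resource x, in update
        steps.  Large ``tau_R`` -> depression-dominant synapses.
    tau_F:
        Facilitation time constant of the utilization u, in update steps.
        Large ``tau_F`` -> facilitation-dominant synapses.
    U_se:
        Baseline fraction of neurotransmitter released per activation,
        in (0, 1]; the resting value of u.
    b:
        Correlation level of the stored (child) patterns with their common
        parent, in [0, 1].
    p:
        Number of stored memory patterns.
    N:
        Number of neurons (used by the stochastic model and by finite-N
        mean-field variants).
    """

    T: float = 1.0
    tau_R: float = 4.0
    tau_F: float = 2.0
    U_se: float = 0.1
    b: float = 0.2
    p: int = 3
    N: int = 10_000

    def __post_init__(self) -> None:
        if not self.T >= MIN_T:
            raise ValueError(f"noise intensity T must be >= {MIN_T}, got {self.T}")
        if self.tau_R < 1:
            raise ValueError(f"tau_R must be >= 1 step, got {self.tau_R}")
        if self.tau_F < 1:
            raise ValueError(f"tau_F must be >= 1 step, got {self.tau_F}")
        if not 0 < self.U_se <= 1:
            raise ValueError(f"U_se must lie in (0, 1], got {self.U_se}")
        if not 0 <= self.b <= 1:
            raise ValueError(f"correlation level b must lie in [0, 1], got {self.b}")
        if self.p < 1 or self.N < 1:
            raise ValueError("p and N must be positive integers")

    @property
    def beta(self) -> float:
        """Inverse noise intensity."""
        return 1.0 / self.T

    def with_T(self, T: float) -> "ModelParams":
        """Copy of these parameters at a different noise intensity."""
        return replace(self, T=float(T))


def response_function(h, T):
    """Firing probability ``g(h) = (1 + tanh(h / T)) / 2``.

    Monotone increasing in the field h, equal to 1/2 at h = 0, and
    saturating at 0 and 1.  ``g(h) + g(-h) = 1``.
    """
    if not T >= MIN_T:
        raise ValueError(f"noise intensity T must be >= {MIN_T}, got {T}")
    return 0.5 * (1.0 + np.tanh(np.asarray(h, dtype=float) / T))


def response_derivative(h, T):
    """Derivative ``g'(h) = (1 - tanh^2(h / T)) / (2 T)`` of the response."""
    if not T >= MIN_T:
        raise ValueError(f"noise intensity T must be >= {MIN_T}, got {T}")
    th = np.tanh(np.asarray(h, dtype=float) / T)
    return 0.5 / T * (1.0 - th * th)
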