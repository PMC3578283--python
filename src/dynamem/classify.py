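"""State classification from overlap data (p = 3).

Fixed points fall into four classes, read off the overlap triple
(M1, M2, M3):

* MEM   -- single-pattern retrieval, (M, M*, M*) with M > M* > 0 up to
           permutation and global sign (six states);
* SMIX  -- symmetric mixture, (Mb, Mb, Mb) with Mb != 0 (two states);
* AMIX  -- asymmetric mixture, (-M'', M', M') with M' > M'' > 0 up to
           permutation and sign (six states);
* PARA  -- paramagnetic, (0, 0, 0).

Oscillatory attractors are binned by the *effective dimension* ED(t): the
number of distinguishable overlap values at step t, at tolerance epsilon
(1e-5 for mean-field time courses).  Its time average MED assigns OS1
(MED = 1, in-phase mixture oscillation), OS2 (1 < MED <= 2, one dominant
pattern oscillating against its inverse) or OS3 (2 < MED <= 3, circulation
among the three patterns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "StateLabel",
    "effective_dimension",
    "mean_effective_dimension",
    "classify_fixed_point",
    "classify_oscillation",
    "EPSILON_ED",
]

#: overlap-equality tolerance for the effective dimension of mean-field orbits
EPSILON_ED = 1e-5

_PAIRS = ((0, 1), (1, 2), (2, 0))


@dataclass(frozen=True)
class StateLabel:
    """Class label with the distinguishing detail, e.g. MEM+1 or AMIX-3.

    ``detail`` is the 0-based index of the distinguished pattern (the
    retrieved one for MEM, the sign-flipped one for AMIX, the dominant one
    for OS2) where applicable; ``sign`` is the overall orientation.  ``med``
    carries the mean effective dimension for oscillatory labels.
    """

    kind: str  # MEM | SMIX | AMIX | PARA | OS1 | OS2 | OS3 | UNCLASSIFIED
    detail: Optional[int] = None
    sign: Optional[int] = None
    med: Optional[float] = None

    @property
    def code(self) -> str:
        """Short serialization code; pattern indices rendered 1-based."""
        if self.kind in ("MEM", "AMIX") and self.detail is not None:
            return f"{self.kind}{'+' if self.sign >= 0 else '-'}{self.detail + 1}"
        if self.kind == "SMIX" and self.sign is not None:
            return f"SMIX{'+' if self.sign >= 0 else '-'}"
        if self.kind == "OS2" and self.detail is not None:
            return f"OS2:{self.detail + 1}"
        return self.kind

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def effective_dimension(M, epsilon: float = EPSILON_ED) -> int:
    """Number of distinguishable values among the three overlaps.

    1 if all pairwise |M^mu - M^nu| < epsilon, 3 if all exceed epsilon,
    2 otherwise.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3,):
        raise NotImplementedError("effective dimension is defined for p = 3 only")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    close = [abs(M[i] - M[j]) < epsilon for i, j in _PAIRS]
    if all(close):
        return 1
    if not any(close):
        return 3
    return 2


def mean_effective_dimension(M_series, epsilon: float = EPSILON_ED,
                             window: Optional[int] = None) -> float:
    """Average ED(t) over the last ``window`` steps of an overlap time course.

    ``M_series`` is an (n_steps, 3) array (an ``OverlapTrace.M`` works).
    """
    M_series = np.asarray(M_series, dtype=float)
    if M_series.ndim != 2 or M_series.shape[1] != 3:
        raise NotImplementedError("mean effective dimension is defined for p = 3 only")
    if window is not None:
        if window < 1:
            raise ValueError("window must be >= 1")
        M_series = M_series[-window:]
    d = np.abs(M_series[:, [0, 1, 2]] - M_series[:, [1, 2, 0]])
    ed = np.where((d < epsilon).all(axis=1), 1, np.where((d > epsilon).all(axis=1), 3, 2))
    return float(ed.mean())


def classify_fixed_point(M, tol_zero: float = 1e-6, tol_equal: float = 1e-6) -> StateLabel:
    """Label a converged fixed point from its overlap triple.

    Sign structure is resolved first, magnitude ordering second; exact ties
    between the competing readings yield UNCLASSIFIED rather than a guess.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3,):
        raise NotImplementedError("fixed-point classification is defined for p = 3 only")

    if np.abs(M).max() < tol_zero:
        return StateLabel("PARA")

    eq = [abs(M[i] - M[j]) < tol_equal for i, j in _PAIRS]
    if all(eq):
        return StateLabel("SMIX", sign=int(np.sign(M.sum())))
    if not any(eq):
        return StateLabel("UNCLASSIFIED")

    # exactly one (or two adjacent) pair equal: identify the distinct index
    pair = _PAIRS[int(np.argmax([abs(M[i] - M[j]) < tol_equal for i, j in _PAIRS]))]
    k = ({0, 1, 2} - set(pair)).pop()
    pair_val = 0.5 * (M[pair[0]] + M[pair[1]])
    distinct = M[k]
    if abs(pair_val) < tol_zero or abs(distinct) < tol_zero:
        return StateLabel("UNCLASSIFIED")
    same_sign = np.sign(distinct) == np.sign(pair_val)
    if same_sign and abs(distinct) > abs(pair_val) + tol_equal:
        return StateLabel("MEM", detail=k, sign=int(np.sign(distinct)))
    if not same_sign and abs(distinct) < abs(pair_val) - tol_equal:
        return StateLabel("AMIX", detail=k, sign=int(np.sign(pair_val)))
    return StateLabel("UNCLASSIFIED")


def classify_oscillation(M_series, epsilon: float = EPSILON_ED,
                         window: Optional[int] = None,
                         amplitude_threshold: float = 1e-3) -> StateLabel:
    """Label a post-transient oscillatory overlap time course as OS1/OS2/OS3.

    Raises ``ValueError`` for traces whose peak-to-peak overlap amplitude is
    below ``amplitude_threshold`` (classify those with
    :func:`classify_fixed_point` instead).  For OS2 the dominant pattern
    (largest amplitude) is recorded; for OS3 the detail is the first pattern
    of the detected circulation order when one exists.
    """
    M_series = np.asarray(M_series, dtype=float)
    if M_series.ndim != 2 or M_series.shape[1] != 3:
        raise NotImplementedError("oscillation classification is defined for p = 3 only")
    if window is not None:
        M_series = M_series[-window:]
    amp = M_series.max(axis=0) - M_series.min(axis=0)
    if amp.max() <= amplitude_threshold:
        raise ValueError(
            f"trace peak-to-peak amplitude {amp.max():.2e} is below the "
            f"oscillation threshold {amplitude_threshold:.2e}"
        )
    med = mean_effective_dimension(M_series, epsilon)
    if med <= 1.0 + 1e-12:
        return StateLabel("OS1", med=med)
    if med <= 2.0 + 1e-12:
        return StateLabel("OS2", detail=int(np.argmax(amp)), med=med)
    return StateLabel("OS3", detail=_circulation_start(M_series), med=med)


def _circulation_start(M_series: np.ndarray) -> Optional[int]:
    """First pattern of the dominance cycle, if the orbit visits all three."""
    dom = np.argmax(np.abs(M_series), axis=1)
    switches = dom[np.flatnonzero(np.diff(dom)) + 1]
    if switches.size and set(np.unique(dom)) == {0, 1, 2}:
        return int(switches[0])
    return None
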