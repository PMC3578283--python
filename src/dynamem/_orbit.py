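"""Long-orbit iteration of the macroscopic map, JIT-compiled when numba is present.

Used by the brute-force attractor scans, which iterate the 3*2^p map for
10^4-10^5 steps per parameter point.  The kernel returns the final state,
per-pattern overlap extrema over the measurement window and (for p = 3) the
mean effective dimension at tolerance ``eps``.
"""

from __future__ import annotations

import numpy as np


def _iterate_kernel(m, X, U, sizes, dot, labels, T, tau_R, tau_F, U_se,
                    n_transient, n_window, eps):
    p = labels.shape[1]
    Mmin = np.full(p, np.inf)
    Mmax = np.full(p, -np.inf)
    ed_sum = 0.0
    for t in range(n_transient + n_window):
        sigma = 2.0 * m * X * U / U_se - 1.0
        h = dot @ (sizes * sigma)
        m_new = 0.5 * (1.0 + np.tanh(h / T))
        X_new = X + (1.0 - X) / tau_R - m * X * U
        U_new = U + (U_se - U) / tau_F + U_se * (1.0 - U) * m
        m, X, U = m_new, X_new, U_new
        if t >= n_transient:
            M = labels.T @ (sizes * (2.0 * m - 1.0))
            for mu in range(p):
                if M[mu] < Mmin[mu]:
                    Mmin[mu] = M[mu]
                if M[mu] > Mmax[mu]:
                    Mmax[mu] = M[mu]
            if p == 3:
                d12 = abs(M[0] - M[1])
                d23 = abs(M[1] - M[2])
                d31 = abs(M[2] - M[0])
                if d12 < eps and d23 < eps and d31 < eps:
                    ed_sum += 1.0
                elif d12 > eps and d23 > eps and d31 > eps:
                    ed_sum += 3.0
                else:
                    ed_sum += 2.0
    med = ed_sum / n_window if n_window > 0 else np.nan
    return m, X, U, Mmin, Mmax, med


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _iterate_fast = njit(_iterate_kernel)
except ImportError:  # pragma: no cover
    _iterate_fast = None


def iterate_orbit(state, spec, params, n_transient: int, n_window: int,
                  eps: float = 1e-5):
    """Iterate the macroscopic map and summarize the measurement window.

    Returns ``(final_state_tuple, Mmin, Mmax, med)`` where the extrema are
    per-pattern overlap minima/maxima over the last ``n_window`` steps and
    ``med`` is the mean effective dimension there (NaN unless p = 3).
    """
    args = (
        state.m.astype(np.float64).copy(),
        state.X.astype(np.float64).copy(),
        state.U.astype(np.float64).copy(),
        spec.sizes.astype(np.float64),
        spec.dot_matrix.astype(np.float64),
        spec.labels.astype(np.float64),
        float(params.T), float(params.tau_R), float(params.tau_F), float(params.U_se),
        int(n_transient), int(n_window), float(eps),
    )
    kernel = _iterate_fast if _iterate_fast is not None else _iterate_kernel
    m, X, U, Mmin, Mmax, med = kernel(*args)
    return (m, X, U), Mmin, Mmax, med
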