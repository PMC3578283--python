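"""Fixed points, spectra, branch continuation, bifurcations, phase diagrams.

The macroscopic map's steady states solve the self-consistency equation

    m_eta = g( sum_eta' p_eta' (eta.eta') (2 m_eta' X(m_eta') U(m_eta') / U_se - 1) )

with X, U slaved to m; stability follows from the spectrum of the analytic
3*2^p Jacobian.  Branches are continued in the noise intensity T.  Branch
families inherit symmetries (all-pattern exchange for SMIX, exchange of the
two non-retrieved patterns for MEM/AMIX), and Newton is run in the
symmetry-fixed subspace: transcritical crossings with symmetry-breaking
branches then no longer make the reduced Jacobian singular, so continuation
passes straight through them while the full spectrum still reports the
crossing.

Bifurcation types on a branch:

* NS -- a complex-conjugate eigenvalue pair crosses |lambda| = 1 (an
  invariant circle is born or absorbed);
* SN -- either a fold terminating the branch in T, or an interior real
  crossing of +1 where a companion pair of fixed points annihilates onto
  the branch from one side;
* TC -- a real crossing of +1 with a transversally intersecting branch
  present on both sides (stability exchange);
* PF -- a real crossing at a spin-flip-symmetric state where a
  symmetry-related pair of branches merges with the trunk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from ._orbit import iterate_orbit
from .classify import EPSILON_ED, StateLabel, classify_fixed_point, classify_oscillation
from .meanfield import (
    SublatticeState,
    macro_mf_step,
    overlaps_from_sublattices,
    steady_state_maps,
)
from .params import ModelParams, response_derivative
from .patterns import SublatticeSpec

__all__ = [
    "FixedPoint",
    "Branch",
    "BifurcationPoint",
    "STABILITY_MARGIN",
    "seed_family",
    "solve_fixed_point",
    "enumerate_fixed_points",
    "jacobian",
    "eigen_stability",
    "continue_branch",
    "detect_bifurcations",
    "oscillation_range",
    "phase_diagram",
]

#: spectral-radius margin below 1 required to call a fixed point stable
STABILITY_MARGIN = 1e-8

#: |Im(lambda)| above which an eigenvalue counts as a complex-pair member
_COMPLEX_TOL = 1e-8


# ---------------------------------------------------------------------------
# fixed points


@dataclass
class FixedPoint:
    """A steady state of the macroscopic map with its local stability data."""

    state: SublatticeState
    params: ModelParams
    spec: SublatticeSpec
    residual: float
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    label: StateLabel

    @property
    def T(self) -> float:
        return self.params.T

    @property
    def overlaps(self) -> np.ndarray:
        return overlaps_from_sublattices(self.state, self.spec)

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(self.eigenvalues).max())


@dataclass
class Branch:
    """Fixed points of one family at increasing (or decreasing) T."""

    parameter: str
    points: list[FixedPoint]
    label: str
    end_reason: str = "range-end"  # range-end | fold | merged | lost

    @property
    def T_values(self) -> np.ndarray:
        return np.array([fp.T for fp in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fp in self.points:
            row: dict = {"T": fp.T}
            for k, mk in enumerate(fp.state.m):
                row[f"m_{k}"] = mk
            for mu, Mmu in enumerate(fp.overlaps):
                row[f"M{mu + 1}"] = Mmu
            row["spectral_radius"] = fp.spectral_radius
            row["stable"] = fp.stable
            row["label"] = fp.label.code
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BifurcationPoint:
    """Critical parameter value with type and the eigenvalue at detection."""

    T: float
    type: str  # SN | NS | TC | PF | real-crossing
    branch_label: str
    eigenvalue: complex

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "type": self.type,
            "branch_label": self.branch_label,
            "leading_eigenvalue_re": self.eigenvalue.real,
            "leading_eigenvalue_im": self.eigenvalue.imag,
        }


def seed_family(spec: SublatticeSpec, c: float = 0.8) -> list[tuple[str, np.ndarray]]:
    """Canonical initial guesses reaching every fixed-point family at p = 3.

    PARA (m = 1/2), six MEM seeds m_eta = (1 + c s eta^mu)/2, two SMIX seeds
    aligned with +-sign(eta^1 + eta^2 + eta^3), and six AMIX seeds with one
    pattern sign-flipped in the mixture.
    """
    eta = spec.labels.astype(float)
    seeds: list[tuple[str, np.ndarray]] = [("PARA", np.full(spec.n_sublattices, 0.5))]
    for mu in range(spec.p):
        for s in (1, -1):
            seeds.append((f"MEM{'+' if s > 0 else '-'}{mu + 1}", (1 + c * s * eta[:, mu]) / 2))
    mix = np.sign(eta.sum(axis=1))
    for s in (1, -1):
        seeds.append((f"SMIX{'+' if s > 0 else '-'}", (1 + c * s * mix) / 2))
    for mu in range(spec.p):
        flipped = eta.copy()
        flipped[:, mu] *= -1
        amix = np.sign(flipped.sum(axis=1))
        for s in (1, -1):
            seeds.append((f"AMIX{'+' if s > 0 else '-'}{mu + 1}", (1 + c * s * amix) / 2))
    return seeds


def _reduced_residual(m: np.ndarray, spec: SublatticeSpec, params: ModelParams) -> np.ndarray:
    """Self-consistency residual g(h(m)) - m with X, U slaved to m."""
    X, U = steady_state_maps(m, params)
    sigma = 2.0 * m * X * U / params.U_se - 1.0
    h = spec.dot_matrix @ (spec.sizes * sigma)
    return 0.5 * (1.0 + np.tanh(h / params.T)) - m


def _pattern_permutation_indices(spec: SublatticeSpec) -> list[np.ndarray]:
    """Sublattice index maps of all p! pattern relabelings."""
    return [spec.permutation_index(perm) for perm in permutations(range(spec.p))]


def _symmetry_classes(spec: SublatticeSpec, m: np.ndarray, tol: float = 1e-6) -> list[np.ndarray]:
    """Orbit classes of the sublattices under the stabilizer subgroup of m.

    Only pattern permutations that also fix the sublattice sizes are
    considered, so ideal and empirical size vectors are both respected.
    """
    keep = []
    for idx in _pattern_permutation_indices(spec):
        if (np.abs(m[idx] - m) < tol).all() and np.allclose(spec.sizes[idx], spec.sizes):
            keep.append(idx)
    n = spec.n_sublattices
    cls = np.arange(n)
    for idx in keep:
        for k in range(n):
            a, b = cls[k], cls[idx[k]]
            if a != b:
                cls[cls == max(a, b)] = min(a, b)
    classes = [np.flatnonzero(cls == c) for c in np.unique(cls)]
    return classes


def solve_fixed_point(
    seed: SublatticeState | np.ndarray,
    spec: SublatticeSpec,
    params: ModelParams,
    tol: float = 1e-11,
    symmetry: Optional[str | Sequence[np.ndarray]] = "auto",
) -> Optional[FixedPoint]:
    """Newton solve of the self-consistent steady state from a seed.

    Works on the reduced m-only system (X, U substituted by their
    steady-state maps); with ``symmetry="auto"`` the solve is constrained to
    the subspace fixed by the seed's pattern-permutation stabilizer.
    Returns None when Newton fails or converges outside [0, 1]^{2^p}.
    """
    m0 = np.asarray(seed.m if isinstance(seed, SublatticeState) else seed, dtype=float)
    if symmetry == "auto":
        classes = _symmetry_classes(spec, m0)
    elif symmetry is None:
        classes = [np.array([k]) for k in range(spec.n_sublattices)]
    else:
        classes = list(symmetry)

    expand = np.zeros((spec.n_sublattices, len(classes)))
    for j, cl in enumerate(classes):
        expand[cl, j] = 1.0
    reps = np.array([cl[0] for cl in classes])

    def fun(y: np.ndarray) -> np.ndarray:
        return _reduced_residual(expand @ y, spec, params)[reps]

    y0 = np.array([m0[cl].mean() for cl in classes])
    sol = root(fun, y0, method="hybr", tol=1e-13)
    if not sol.success:
        return None
    m = expand @ sol.x
    if (m < -1e-9).any() or (m > 1 + 1e-9).any():
        return None
    m = np.clip(m, 0.0, 1.0)
    resid = float(np.abs(_reduced_residual(m, spec, params)).max())
    if resid > tol:
        return None
    state = SublatticeState.from_activity(m, params)
    return _finalize_fixed_point(state, spec, params, resid)


def _finalize_fixed_point(state: SublatticeState, spec: SublatticeSpec,
                          params: ModelParams, resid: float) -> FixedPoint:
    eigvals = np.linalg.eigvals(jacobian(state, spec, params))
    rad = float(np.abs(eigvals).max())
    label = classify_fixed_point(overlaps_from_sublattices(state, spec))
    return FixedPoint(
        state=state, params=params, spec=spec, residual=resid,
        eigenvalues=eigvals,
        stable=rad < 1.0 - STABILITY_MARGIN,
        marginal=abs(rad - 1.0) <= STABILITY_MARGIN,
        label=label,
    )


def enumerate_fixed_points(
    spec: SublatticeSpec,
    params: ModelParams,
    extra_random: int = 0,
    rng: Optional[np.random.Generator] = None,
    tol: float = 1e-11,
) -> list[FixedPoint]:
    """Distinct fixed points reachable from the canonical seed family.

    Optionally adds uniform-random seeds (solved without symmetry
    constraints) to pick up fully asymmetric solutions.
    """
    found: list[FixedPoint] = []

    def push(fp: Optional[FixedPoint]) -> None:
        if fp is None:
            return
        if all(np.abs(fp.state.m - q.state.m).max() > 1e-7 for q in found):
            found.append(fp)

    for _, m0 in seed_family(spec):
        push(solve_fixed_point(m0, spec, params, tol=tol))
    if extra_random:
        rng = rng or np.random.default_rng()
        for _ in range(extra_random):
            push(solve_fixed_point(rng.uniform(0, 1, spec.n_sublattices), spec, params,
                                   tol=tol, symmetry=None))
    return found


# ---------------------------------------------------------------------------
# Jacobian and spectra


def jacobian(state: SublatticeState, spec: SublatticeSpec, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the macroscopic map at an arbitrary state.

    Block structure (sublattices in fixed label order; n = 2^p):

        [ dFm/dm   dFm/dX   dFm/dU ]        full n x n blocks
        [ dFX/dm   dFX/dX   dFX/dU ]        diagonal blocks
        [ dFU/dm     0      dFU/dU ]        diagonal blocks

    The activity rows share the factor g'(h_eta) p_eta' (eta.eta') with the
    remaining factor 2 X U / U_se, 2 m U / U_se or 2 m X / U_se depending on
    the differentiation variable.
    """
    n = spec.n_sublattices
    m, X, U = state.m, state.X, state.U
    sigma = 2.0 * m * X * U / params.U_se - 1.0
    h = spec.dot_matrix @ (spec.sizes * sigma)
    gp = response_derivative(h, params.T)

    W = gp[:, None] * spec.dot_matrix * spec.sizes[None, :]
    K = np.zeros((3 * n, 3 * n))
    K[:n, :n] = W * (2.0 * X * U / params.U_se)[None, :]
    K[:n, n : 2 * n] = W * (2.0 * m * U / params.U_se)[None, :]
    K[:n, 2 * n :] = W * (2.0 * m * X / params.U_se)[None, :]

    idx = np.arange(n)
    K[n + idx, idx] = -U * X
    K[n + idx, n + idx] = (1.0 - 1.0 / params.tau_R) - m * U
    K[n + idx, 2 * n + idx] = -m * X
    K[2 * n + idx, idx] = params.U_se * (1.0 - U)
    K[2 * n + idx, 2 * n + idx] = (1.0 - 1.0 / params.tau_F) - params.U_se * m
    return K


def eigen_stability(fp: FixedPoint, margin: float = STABILITY_MARGIN):
    """Spectrum, stability flag and leading (largest-modulus) eigenvalue."""
    lead = fp.eigenvalues[np.argmax(np.abs(fp.eigenvalues))]
    return fp.eigenvalues, float(np.abs(lead)) < 1.0 - margin, complex(lead)


def _leading_real(eigvals: np.ndarray) -> float:
    re = eigvals[np.abs(eigvals.imag) <= _COMPLEX_TOL].real
    return float(re.max()) if re.size else -np.inf


def _leading_complex_modulus(eigvals: np.ndarray) -> float:
    cx = eigvals[np.abs(eigvals.imag) > _COMPLEX_TOL]
    return float(np.abs(cx).max()) if cx.size else -np.inf


# ---------------------------------------------------------------------------
# continuation


def continue_branch(
    fp0: FixedPoint,
    T_stop: float,
    step: float = 5e-3,
    min_step: float = 1e-6,
    jump_tol: float = 0.05,
    tol: float = 1e-11,
) -> Branch:
    """Natural-parameter continuation of a fixed-point branch in T.

    Steps from ``fp0.T`` toward ``T_stop`` with adaptive halving near folds;
    each accepted point must stay within ``jump_tol`` (max-norm on m) of its
    predecessor and keep the branch's state class.  The symmetry classes of
    the starting point are reused for the whole branch.  Termination reasons:
    ``range-end`` (reached ``T_stop``), ``fold`` (step underflow),
    ``merged`` (the solution slid onto a different state class, e.g. a
    mixture branch coalescing with the paramagnetic trunk).
    """
    direction = 1.0 if T_stop >= fp0.T else -1.0
    classes = _symmetry_classes(fp0.spec, fp0.state.m)
    spec, base_step = fp0.spec, step
    points = [fp0]
    end_reason = "range-end"
    T, m_prev = fp0.T, fp0.state.m
    m_prev2: Optional[np.ndarray] = None

    while direction * (T_stop - T) > 1e-12:
        h_step = min(step, abs(T_stop - T))
        T_next = T + direction * h_step
        params = fp0.params.with_T(T_next)
        fp = solve_fixed_point(m_prev, spec, params, tol=tol, symmetry=classes)
        if fp is None and m_prev2 is not None:
            # isolated singular point (e.g. transcritical): extrapolated seed
            fp = solve_fixed_point(2 * m_prev - m_prev2, spec, params, tol=tol,
                                   symmetry=classes)
        if fp is not None and np.abs(fp.state.m - m_prev).max() <= jump_tol:
            if fp.label.kind != fp0.label.kind:
                end_reason = "merged"
                points.append(fp)
                break
            points.append(fp)
            T, m_prev2, m_prev = T_next, m_prev, fp.state.m
            step = min(base_step, step * 1.5)
            continue
        step *= 0.5
        if step < min_step:
            end_reason = "fold"
            break
    return Branch(parameter="T", points=points, label=fp0.label.code, end_reason=end_reason)


def _refine_fold(branch: Branch, tol_T: float = 1e-6) -> Optional[FixedPoint]:
    """Walk the branch past its last point to the fold with step halving.

    Returns the fixed point closest to the fold (existence bisection:
    Newton succeeds below the fold, fails or jumps branch above it).
    """
    if len(branch.points) < 2:
        return None
    last = branch.points[-1]
    direction = np.sign(branch.points[-1].T - branch.points[0].T) or 1.0
    spec, classes = last.spec, _symmetry_classes(last.spec, last.state.m)
    T, m_prev = last.T, last.state.m
    fp_best = last
    step = 2.5e-3
    while step > tol_T:
        params = last.params.with_T(T + direction * step)
        fp = solve_fixed_point(m_prev, spec, params, symmetry=classes)
        if (
            fp is not None
            and np.abs(fp.state.m - m_prev).max() < 0.05
            and fp.label.kind == last.label.kind
        ):
            T, m_prev, fp_best = fp.T, fp.state.m, fp
        else:
            step *= 0.5
    return fp_best


# ---------------------------------------------------------------------------
# bifurcation detection


def detect_bifurcations(
    branch: Branch,
    refine_tol: float = 1e-4,
    classify_types: bool = True,
) -> list[BifurcationPoint]:
    """Locate and type eigenvalue crossings of the unit circle along a branch.

    Complex-pair modulus crossings are NS.  Real crossings of +1 are
    bisected in T and typed from branch geometry and symmetry (see module
    docstring); ambiguous ones are reported as ``real-crossing``.  A branch
    that terminated in a fold contributes an SN point at the refined fold T.
    """
    if len(branch.points) < 3:
        raise ValueError("bifurcation detection needs a branch with at least 3 points")
    out: list[BifurcationPoint] = []

    for f, kind in ((_leading_real, "real"), (_leading_complex_modulus, "ns")):
        target = 1.0
        for fp1, fp2 in zip(branch.points, branch.points[1:]):
            f1, f2 = f(fp1.eigenvalues) - target, f(fp2.eigenvalues) - target
            if not (np.isfinite(f1) or np.isfinite(f2)):
                continue
            if (f1 < 0) != (f2 < 0):
                fp_c = _bisect_crossing(fp1, fp2, f, target, refine_tol)
                if fp_c is None:
                    continue
                lead = _critical_eigenvalue(fp_c, kind)
                btype = (
                    "NS" if kind == "ns"
                    else _classify_real_crossing(fp_c) if classify_types
                    else "real-crossing"
                )
                out.append(BifurcationPoint(T=fp_c.T, type=btype,
                                            branch_label=branch.label, eigenvalue=lead))

    if branch.end_reason == "fold":
        fp_fold = _refine_fold(branch)
        if fp_fold is not None:
            # near the fold, natural continuation can slip onto the returning
            # partner branch, producing a spurious interior real crossing at
            # essentially the fold T: keep only the SN there
            out = [bp for bp in out
                   if bp.type == "NS" or abs(bp.T - fp_fold.T) > 2.5e-3]
            out.append(BifurcationPoint(
                T=fp_fold.T, type="SN", branch_label=branch.label,
                eigenvalue=_critical_eigenvalue(fp_fold, "real"),
            ))
    return sorted(out, key=lambda bp: bp.T)


def _critical_eigenvalue(fp: FixedPoint, kind: str) -> complex:
    ev = fp.eigenvalues
    if kind == "ns":
        cx = ev[np.abs(ev.imag) > _COMPLEX_TOL]
        pool = cx if cx.size else ev
        return complex(pool[np.argmax(np.abs(pool))])
    re = ev[np.abs(ev.imag) <= _COMPLEX_TOL]
    pool = re if re.size else ev
    return complex(pool[np.argmin(np.abs(pool - 1.0))])


def _bisect_crossing(fp1: FixedPoint, fp2: FixedPoint,
                     f: Callable[[np.ndarray], float], target: float,
                     refine_tol: float) -> Optional[FixedPoint]:
    spec = fp1.spec
    classes = _symmetry_classes(spec, fp1.state.m)
    lo, hi = fp1, fp2
    sign_lo = (f(lo.eigenvalues) - target) < 0
    while abs(hi.T - lo.T) > refine_tol:
        T_mid = 0.5 * (lo.T + hi.T)
        fp_mid = solve_fixed_point(lo.state.m, spec, lo.params.with_T(T_mid),
                                   symmetry=classes)
        if fp_mid is None:
            fp_mid = solve_fixed_point(hi.state.m, spec, hi.params.with_T(T_mid),
                                       symmetry=classes)
        if fp_mid is None:
            return None
        if ((f(fp_mid.eigenvalues) - target) < 0) == sign_lo:
            lo = fp_mid
        else:
            hi = fp_mid
    return lo if abs(f(lo.eigenvalues) - target) < abs(f(hi.eigenvalues) - target) else hi


def _is_sign_flip_invariant(fp: FixedPoint, tol: float = 1e-6) -> bool:
    """True for the symmetric trunk: invariant under the spin flip m -> 1 - m."""
    return bool(np.abs(1.0 - 2.0 * fp.state.m).max() < tol)


def _classify_real_crossing(fp_c: FixedPoint, delta_T: float = 0.01,
                            eps: float = 0.03) -> str:
    """Type an interior real crossing: PF, TC, SN or real-crossing.

    A spin-flip-symmetric critical state is a pitchfork of the trunk.
    Otherwise companion fixed points are probed near the critical point
    along the critical eigendirection on both sides of T*: companions
    passing through (both sides) indicate a transcritical exchange;
    companions on one side only, a pair annihilating onto the branch
    (saddle-node collision); none, an unclassified crossing.
    """
    if _is_sign_flip_invariant(fp_c):
        return "PF"
    spec, params = fp_c.spec, fp_c.params
    K = jacobian(fp_c.state, spec, params)
    w, V = np.linalg.eig(K)
    v = np.real(V[: spec.n_sublattices, np.argmin(np.abs(w - 1.0))])
    if np.abs(v).max() < 1e-12:
        return "real-crossing"
    v = v / np.abs(v).max()

    sides = []
    for dT in (-delta_T, +delta_T):
        found = False
        base = solve_fixed_point(fp_c.state.m, spec, params.with_T(params.T + dT),
                                 symmetry="auto")
        for s in (+eps, -eps):
            m_seed = np.clip(fp_c.state.m + s * v, 0.0, 1.0)
            cand = solve_fixed_point(m_seed, spec, params.with_T(params.T + dT),
                                     symmetry=None)
            if cand is not None and base is not None:
                dist = np.abs(cand.state.m - base.state.m).max()
                # a genuine companion is distinct but still local
                if 1e-4 < dist < 0.2:
                    found = True
                    break
        sides.append(found)
    if all(sides):
        return "TC"
    if any(sides):
        return "SN"
    return "real-crossing"


# ---------------------------------------------------------------------------
# brute-force attractor scans


def oscillation_range(
    spec: SublatticeSpec,
    params_base: ModelParams,
    T_grid: Sequence[float],
    transient: int = 5000,
    window: int = 10_000,
    amplitude_threshold: float = 1e-3,
    inherit: bool = True,
    fresh_seeds: Sequence[np.ndarray] = (),
    state0: Optional[SublatticeState] = None,
    eps: float = EPSILON_ED,
) -> pd.DataFrame:
    """Attractor summary (fixed point vs oscillation) along an ordered T grid.

    At each T the previous attractor is inherited as initial condition
    (tracking subcritical oscillations into their bistable range) and any
    ``fresh_seeds`` (activity vectors, X/U slaved) are run as well; the cell
    is oscillatory when any candidate's post-transient peak-to-peak overlap
    amplitude exceeds ``amplitude_threshold``.  Columns: T, oscillating,
    amplitude, med, label plus per-pattern overlap extrema.
    """
    rows = []
    current = state0
    for T in T_grid:
        params = params_base.with_T(float(T))
        candidates: list[SublatticeState] = []
        if inherit and current is not None:
            candidates.append(current)
        candidates += [SublatticeState.from_activity(np.asarray(m0, float), params)
                       for m0 in fresh_seeds]
        if not candidates:
            raise ValueError("no initial condition: provide state0 or fresh_seeds")

        best = None
        for cand in candidates:
            (m, X, U), Mmin, Mmax, med = iterate_orbit(cand, spec, params,
                                                       transient, window, eps)
            amp = float((Mmax - Mmin).max())
            summary = (SublatticeState(m, X, U), Mmin, Mmax, med, amp)
            if amp > amplitude_threshold:
                best = summary
                break  # inherited attractor (listed first) wins
            if best is None:
                best = summary
        state_f, Mmin, Mmax, med, amp = best
        oscillating = amp > amplitude_threshold
        if oscillating:
            label = _os_label_from_med(med)
        else:
            label = classify_fixed_point(0.5 * (Mmin + Mmax), tol_zero=1e-3,
                                         tol_equal=1e-3).kind
        row = {"T": float(T), "oscillating": oscillating, "amplitude": amp,
               "med": med, "label": label}
        for mu in range(spec.p):
            row[f"Mmin{mu + 1}"] = Mmin[mu]
            row[f"Mmax{mu + 1}"] = Mmax[mu]
        rows.append(row)
        current = state_f
    return pd.DataFrame(rows)


def _os_label_from_med(med: float) -> str:
    if not np.isfinite(med):
        return "OS?"
    if med <= 1.0 + 1e-12:
        return "OS1"
    if med <= 2.0 + 1e-12:
        return "OS2"
    return "OS3"


def oscillation_band(
    spec: SublatticeSpec,
    params_base: ModelParams,
    T_start: float,
    T_stop: float,
    dT: float = 1e-3,
    seed_m: Optional[np.ndarray] = None,
    require_med: Optional[float] = None,
    **kwargs,
) -> Optional[float]:
    """Endpoint of an oscillatory band by orbit inheritance.

    Sweeps from ``T_start`` (inside the band) toward ``T_stop`` in steps of
    ``dT``, inheriting the orbit, and returns the last T at which the
    attractor still oscillates (optionally also requiring MED <=
    ``require_med``, e.g. 1 to track an in-phase band).  None if the first
    point already fails.
    """
    direction = 1.0 if T_stop >= T_start else -1.0
    grid = np.arange(T_start, T_stop + direction * 1e-12, direction * dT)
    state0 = SublatticeState.from_activity(seed_m, params_base.with_T(T_start)) \
        if seed_m is not None else None
    df = oscillation_range(spec, params_base, grid, state0=state0, **kwargs)
    ok = df["oscillating"].to_numpy()
    if require_med is not None:
        ok &= df["med"].to_numpy() <= require_med + 1e-9
    # stop at the first failure; the band endpoint is the last T before it
    bad = np.flatnonzero(~ok)
    last = (bad[0] - 1) if bad.size else len(ok) - 1
    if last < 0:
        return None
    return float(df["T"].iloc[last])


# ---------------------------------------------------------------------------
# phase diagrams


_AXIS_FIELDS = {"T": "T", "tau_R": "tau_R", "tau_F": "tau_F", "U_se": "U_se", "b": "b"}


@dataclass
class PhaseDiagramGrid:
    """Long-format cell table plus bifurcation-boundary midpoints per flag."""

    table: pd.DataFrame
    axis1: str
    axis2: str
    boundaries: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


def phase_diagram(
    spec: SublatticeSpec,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    params_base: ModelParams,
    transient: int = 2000,
    window: int = 4000,
    n_random_starts: int = 4,
    rng: Optional[np.random.Generator] = None,
    amplitude_threshold: float = 1e-3,
) -> PhaseDiagramGrid:
    """Brute-force phase diagram over two parameter axes.

    Each cell enumerates fixed points from the canonical seed family
    (stability flags per class) and runs short orbits from canonical plus
    random starts to detect coexisting oscillatory states (OS1/OS2/OS3
    presence).  Boundaries are cell-edge midpoints where a stability flag
    flips between neighbors.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        if name not in _AXIS_FIELDS:
            raise ValueError(f"unknown phase-diagram axis {name!r}")
    rng = rng or np.random.default_rng(0)

    rows = []
    for v1 in grid1:
        for v2 in grid2:
            params = replace(params_base, **{name1: float(v1), name2: float(v2)})
            cell_spec = SublatticeSpec.ideal(params.b, spec.p) if "b" in (name1, name2) else spec
            flags = _cell_flags(cell_spec, params, transient, window,
                                n_random_starts, rng, amplitude_threshold)
            rows.append({name1: float(v1), name2: float(v2)} | flags)
    table = pd.DataFrame(rows)

    flag_cols = [c for c in table.columns if c not in (name1, name2)]
    boundaries: dict[str, list[tuple[float, float]]] = {c: [] for c in flag_cols}
    pivot = {c: table.pivot(index=name2, columns=name1, values=c).to_numpy()
             for c in flag_cols}
    g1, g2 = np.asarray(grid1, float), np.asarray(grid2, float)
    for c in flag_cols:
        z = pivot[c]
        for i in range(z.shape[0]):
            for j in range(z.shape[1] - 1):
                if z[i, j] != z[i, j + 1]:
                    boundaries[c].append((0.5 * (g1[j] + g1[j + 1]), g2[i]))
        for i in range(z.shape[0] - 1):
            for j in range(z.shape[1]):
                if z[i, j] != z[i + 1, j]:
                    boundaries[c].append((g1[j], 0.5 * (g2[i] + g2[i + 1])))
    return PhaseDiagramGrid(table=table, axis1=name1, axis2=name2, boundaries=boundaries)


def _cell_flags(spec, params, transient, window, n_random, rng, amp_thr) -> dict:
    flags = {f"{k}_stable": False for k in ("MEM", "SMIX", "AMIX", "PARA")}
    for fp in enumerate_fixed_points(spec, params):
        kind = fp.label.kind
        if fp.stable and kind in ("MEM", "SMIX", "AMIX", "PARA"):
            flags[f"{kind}_stable"] = True

    for k in ("OS1", "OS2", "OS3"):
        flags[k] = False
    starts = [m for _, m in seed_family(spec, c=0.6)]
    starts += [rng.uniform(0, 1, spec.n_sublattices) for _ in range(n_random)]
    for m0 in starts:
        state = SublatticeState.from_activity(m0, params)
        _, Mmin, Mmax, med = iterate_orbit(state, spec, params, transient, window)
        if float((Mmax - Mmin).max()) > amp_thr:
            flags[_os_label_from_med(med)] = True
    return flags
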