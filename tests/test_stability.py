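import numpy as np
import pytest

import dynamem as dm
from dynamem.meanfield import macro_mf_step
from dynamem.stability import _reduced_residual


def finite_difference_jacobian(state, spec, params, h=1e-6):
    z0 = state.as_vector()

    def F(z):
        return macro_mf_step(dm.SublatticeState.from_vector(z), spec, params).as_vector()

    J = np.zeros((z0.size, z0.size))
    for i in range(z0.size):
        zp, zm = z0.copy(), z0.copy()
        zp[i] += h
        zm[i] -= h
        J[:, i] = (F(zp) - F(zm)) / (2 * h)
    return J


def random_admissible_state(rng, params):
    m = rng.uniform(0.02, 0.98, 8)
    X = rng.uniform(0.1, 1.0, 8)
    U = rng.uniform(params.U_se, 0.95, 8)
    return dm.SublatticeState(m, X, U)


class TestJacobian:
    def test_matches_finite_difference_at_random_states(self, spec, rng):
        for tau_R, tau_F in [(4, 2), (10, 2), (4, 24)]:
            params = dm.ModelParams(T=0.7, tau_R=tau_R, tau_F=tau_F)
            for _ in range(5):
                state = random_admissible_state(rng, params)
                K = dm.jacobian(state, spec, params)
                K_fd = finite_difference_jacobian(state, spec, params)
                assert np.abs(K - K_fd).max() < 1e-5

    def test_rest_state_diagonal_blocks(self, spec):
        params = dm.ModelParams(T=0.5, tau_R=4, tau_F=2)
        state = dm.SublatticeState.rest(spec, params, m=0.0)
        K = dm.jacobian(state, spec, params)
        assert np.allclose(np.diag(K[8:16, 8:16]), 1 - 1 / params.tau_R)
        assert np.allclose(np.diag(K[16:24, 16:24]), 1 - 1 / params.tau_F)

    def test_utilization_resource_block_vanishes(self, spec, rng):
        params = dm.ModelParams(T=0.9, tau_R=6, tau_F=8)
        state = random_admissible_state(rng, params)
        K = dm.jacobian(state, spec, params)
        assert np.abs(K[16:24, 8:16]).max() == 0.0


class TestSolveFixedPoint:
    def test_paramagnetic_solution(self, spec, seeds):
        fp = dm.solve_fixed_point(seeds["PARA"], spec, dm.ModelParams(T=0.9))
        assert fp.label.kind == "PARA"
        assert np.abs(fp.overlaps).max() < 1e-10
        assert fp.residual < 1e-11

    def test_memory_state_structure(self, spec, seeds):
        # MEM overlaps have the form (M, M*, M*) with M > M* > 0
        fp = dm.solve_fixed_point(seeds["MEM+1"], spec,
                                  dm.ModelParams(T=1.0, tau_R=4, tau_F=2))
        M = fp.overlaps
        assert fp.label.code == "MEM+1"
        assert M[0] > M[1] > 0 and M[1] == pytest.approx(M[2], abs=1e-10)
        assert fp.stable

    def test_memory_state_gone_past_fold(self, spec, seeds):
        # past the fold near T ~ 1.25 no memory fixed point remains
        fp = dm.solve_fixed_point(seeds["MEM+1"], spec,
                                  dm.ModelParams(T=1.3, tau_R=4, tau_F=2))
        assert fp is None or fp.label.kind != "MEM"

    def test_paramagnetic_stable_at_high_noise(self, spec, seeds):
        fp = dm.solve_fixed_point(seeds["PARA"], spec,
                                  dm.ModelParams(T=10.0, tau_R=4, tau_F=2))
        _, stable, lead = dm.eigen_stability(fp)
        assert stable and abs(lead) < 1

    def test_six_fold_memory_orbit(self, spec, seeds):
        # pattern permutations and the spin flip generate all six MEM states
        params = dm.ModelParams(T=0.9, tau_R=4, tau_F=2)
        fp = dm.solve_fixed_point(seeds["MEM+1"], spec, params)
        images = []
        for perm in [(0, 1, 2), (1, 0, 2), (2, 1, 0)]:
            base = dm.permute_state(fp.state, spec, perm)
            for m in (base.m, 1 - base.m):
                assert np.abs(_reduced_residual(m, spec, params)).max() < 1e-8
                images.append(dm.classify_fixed_point(
                    dm.overlaps_from_sublattices(
                        dm.SublatticeState.from_activity(m, params), spec)).code)
        assert sorted(images) == ["MEM+1", "MEM+2", "MEM+3", "MEM-1", "MEM-2", "MEM-3"]

    def test_enumeration_finds_all_fifteen(self, spec):
        fps = dm.enumerate_fixed_points(spec, dm.ModelParams(T=0.2, tau_R=4, tau_F=2))
        codes = sorted(fp.label.code for fp in fps)
        assert len(codes) == 15
        assert codes.count("PARA") == 1
        assert sum(c.startswith("MEM") for c in codes) == 6
        assert sum(c.startswith("AMIX") for c in codes) == 6


class TestContinuation:
    def test_branch_is_reproducible_in_reverse(self, spec, seeds):
        params = dm.ModelParams(T=0.8, tau_R=4, tau_F=2)
        fp0 = dm.solve_fixed_point(seeds["MEM+1"], spec, params)
        up = dm.continue_branch(fp0, 1.0)
        back = dm.continue_branch(up.points[-1], 0.8)
        assert abs(back.points[-1].T - fp0.T) < 1e-9
        assert np.abs(back.points[-1].state.m - fp0.state.m).max() < 1e-6

    def test_memory_branch_ends_in_fold(self, spec, seeds):
        fp0 = dm.solve_fixed_point(seeds["MEM+1"], spec,
                                   dm.ModelParams(T=1.1, tau_R=4, tau_F=2))
        branch = dm.continue_branch(fp0, 1.5)
        assert branch.end_reason == "fold"
        assert branch.points[-1].T == pytest.approx(1.248, abs=0.005)

    def test_mixture_branch_merges_with_trunk(self, spec, seeds):
        fp0 = dm.solve_fixed_point(seeds["SMIX+"], spec,
                                   dm.ModelParams(T=1.3, tau_R=4, tau_F=2))
        branch = dm.continue_branch(fp0, 1.6)
        assert branch.end_reason == "merged"
        assert branch.points[-1].T == pytest.approx(1.49, abs=0.01)

    def test_branch_frame_schema(self, spec, seeds):
        fp0 = dm.solve_fixed_point(seeds["PARA"], spec, dm.ModelParams(T=1.0))
        df = dm.continue_branch(fp0, 1.1).to_frame()
        assert {"T", "M1", "spectral_radius", "stable", "label"} <= set(df.columns)


class TestBifurcationDetection:
    def test_transcritical_on_mixture_branch(self, spec, seeds):
        fp0 = dm.solve_fixed_point(seeds["SMIX+"], spec,
                                   dm.ModelParams(T=0.7, tau_R=4, tau_F=2))
        branch = dm.continue_branch(fp0, 0.9)
        points = dm.detect_bifurcations(branch)
        assert len(points) == 1
        assert points[0].type == "TC"
        assert points[0].T == pytest.approx(0.781, abs=0.005)
        assert abs(points[0].eigenvalue.imag) < 1e-6

    def test_neimark_sacker_on_depressing_memory_branch(self, spec, seeds):
        fp0 = dm.solve_fixed_point(seeds["MEM+1"], spec,
                                   dm.ModelParams(T=0.45, tau_R=10, tau_F=2))
        branch = dm.continue_branch(fp0, 0.62)
        ns = [bp for bp in dm.detect_bifurcations(branch) if bp.type == "NS"]
        assert ns and ns[0].T == pytest.approx(0.576, abs=0.005)
        assert abs(ns[0].eigenvalue.imag) > 1e-3  # genuinely complex pair
        assert abs(ns[0].eigenvalue) == pytest.approx(1.0, abs=1e-3)

    def test_refinement_is_monotone(self, spec, seeds):
        # halving the refinement tolerance moves the detected T by less than
        # the previous tolerance
        fp0 = dm.solve_fixed_point(seeds["SMIX+"], spec,
                                   dm.ModelParams(T=0.7, tau_R=4, tau_F=2))
        branch = dm.continue_branch(fp0, 0.9)
        T_coarse = dm.detect_bifurcations(branch, refine_tol=1e-3)[0].T
        T_fine = dm.detect_bifurcations(branch, refine_tol=5e-4)[0].T
        assert abs(T_fine - T_coarse) <= 1e-3


class TestOscillationScan:
    def test_oscillation_detected_in_depressing_regime(self, spec, seeds):
        params = dm.ModelParams(T=1.0, tau_R=10, tau_F=2)
        df = dm.oscillation_range(
            spec, params, [0.9, 0.95, 1.0],
            transient=3000, window=5000, fresh_seeds=[seeds["MEM+1"]],
        )
        assert df["oscillating"].all()
        assert (df["amplitude"] > 0.1).all()

    def test_fixed_point_regime_not_oscillatory(self, spec, seeds):
        params = dm.ModelParams(T=1.0, tau_R=4, tau_F=2)
        df = dm.oscillation_range(
            spec, params, [0.9, 1.0],
            transient=2000, window=3000, fresh_seeds=[seeds["MEM+1"]],
        )
        assert not df["oscillating"].any()
        assert (df["label"] == "MEM").all()


class TestPhaseDiagram:
    def test_toy_grid_shape_and_flags(self, spec):
        params = dm.ModelParams(T=0.5, tau_R=4, tau_F=2)
        grid = dm.phase_diagram(
            spec, ("tau_R", [4.0, 10.0]), ("T", [0.3, 0.9, 1.7]), params,
            transient=2000, window=3000, n_random_starts=2,
            rng=np.random.default_rng(0),
        )
        assert len(grid.table) == 6
        t = grid.table
        # pseudo-constant column: memory stable at low noise, gone at high noise
        col = t[t["tau_R"] == 4.0].sort_values("T")
        assert col["MEM_stable"].tolist() == [True, True, False]
        assert col["PARA_stable"].tolist() == [False, False, True]
        # depression destabilizes retrieval and creates oscillations
        dep = t[(t["tau_R"] == 10.0) & (t["T"] == 0.9)].iloc[0]
        assert not dep["MEM_stable"]
        assert dep[["OS1", "OS2", "OS3"]].any()
        # stability flips produce boundary midpoints
        assert grid.boundaries["MEM_stable"]
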