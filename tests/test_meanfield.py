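import numpy as np
import pytest

import dynamem as dm
from dynamem.meanfield import macro_field, save_trajectory_csv
from dynamem.stability import _reduced_residual


class TestSteadyStateMaps:
    def test_rest(self):
        params = dm.ModelParams(T=0.5)
        X, U = dm.steady_state_maps(0.0, params)
        assert X == pytest.approx(1.0) and U == pytest.approx(params.U_se)

    def test_hand_arithmetic(self):
        params = dm.ModelParams(T=0.5, tau_R=4, tau_F=2, U_se=0.1)
        X, U = dm.steady_state_maps(0.5, params)
        assert U == pytest.approx(0.1 * 2 / 1.1)
        assert X == pytest.approx(1 / (1 + 4 * (0.1 * 2 / 1.1) * 0.5))

    def test_full_facilitation_limit(self):
        params = dm.ModelParams(T=0.5, tau_F=1e9)
        _, U = dm.steady_state_maps(1.0, params)
        assert U == pytest.approx(1.0, abs=1e-6)

    def test_consistent_with_iterated_synapse_update(self):
        # X(m), U(m) are the fixed point of the X/U update at frozen activity
        params = dm.ModelParams(T=0.5, tau_R=6, tau_F=3, U_se=0.2)
        m = 0.37
        X, U = 1.0, params.U_se
        for _ in range(2000):
            X, U = (
                X + (1 - X) / params.tau_R - m * X * U,
                U + (params.U_se - U) / params.tau_F + params.U_se * (1 - U) * m,
            )
        Xbar, Ubar = dm.steady_state_maps(m, params)
        assert X == pytest.approx(Xbar, abs=1e-12) and U == pytest.approx(Ubar, abs=1e-12)


class TestMacroMap:
    def test_paramagnetic_state_is_fixed(self, spec):
        # m = 1/2 everywhere: symmetric sizes cancel the field exactly
        params = dm.ModelParams(T=0.73, tau_R=5, tau_F=3)
        state = dm.SublatticeState.from_activity(np.full(8, 0.5), params)
        new = dm.macro_mf_step(state, spec, params)
        assert np.abs(new.as_vector() - state.as_vector()).max() < 1e-15

    def test_rest_synapses_stay_at_rest(self, spec):
        params = dm.ModelParams(T=0.5)
        state = dm.SublatticeState.rest(spec, params, m=0.0)
        new = dm.macro_mf_step(state, spec, params)
        assert np.allclose(new.X, 1.0) and np.allclose(new.U, params.U_se)

    def test_range_preservation_long_run(self, spec):
        from dynamem._orbit import iterate_orbit

        params = dm.ModelParams(T=0.9, tau_R=10, tau_F=2)
        state = dm.SublatticeState.from_activity(
            np.random.default_rng(1).uniform(0, 1, 8), params
        )
        (m, X, U), Mmin, Mmax, _ = iterate_orbit(state, spec, params, 0, 100_000)
        dm.SublatticeState(m, X, U).validate(params)
        assert Mmin.min() >= -1 and Mmax.max() <= 1

    def test_fixed_points_reproduce_under_step(self, spec, seeds):
        params = dm.ModelParams(T=0.6, tau_R=4, tau_F=2)
        fp = dm.solve_fixed_point(seeds["MEM+1"], spec, params)
        new = dm.macro_mf_step(fp.state, spec, params)
        assert np.abs(new.as_vector() - fp.state.as_vector()).max() < 1e-10

    def test_inversion_pairing_of_fixed_points(self, spec):
        # for every fixed point, m'(eta) = 1 - m(-eta) is also a fixed point
        params = dm.ModelParams(T=0.43, tau_R=4, tau_F=2)
        fps = dm.enumerate_fixed_points(spec, params)
        assert len(fps) >= 10
        for fp in fps:
            partner = dm.inversion_partner(fp.state, spec, params)
            assert np.abs(_reduced_residual(partner.m, spec, params)).max() < 1e-8


class TestOverlaps:
    def test_perfect_retrieval(self, spec):
        m = (spec.labels[:, 0] + 1) / 2  # active exactly where pattern 1 is +1
        state = dm.SublatticeState(m.astype(float), np.ones(8), np.full(8, 0.1))
        M = dm.overlaps_from_sublattices(state, spec)
        assert M[0] == pytest.approx(1.0)

    def test_paramagnetic_overlaps_vanish(self, spec):
        state = dm.SublatticeState(np.full(8, 0.5), np.ones(8), np.full(8, 0.1))
        assert np.abs(dm.overlaps_from_sublattices(state, spec)).max() < 1e-15

    def test_micro_macro_overlap_identity(self, rng):
        # sublattice-constant microscopic state: both overlap formulas agree
        pat = dm.generate_patterns(800, 3, 0.2, seed=17)
        sub = dm.build_sublattices(pat)
        m_eta = rng.uniform(0, 1, 8)
        s_micro = m_eta[sub.membership]  # fractional "activity" is fine here
        M_micro = pat.children @ (2 * s_micro - 1) / pat.N
        state = dm.SublatticeState(m_eta, np.ones(8), np.full(8, 0.1))
        M_macro = dm.overlaps_from_sublattices(state, sub)
        assert np.allclose(M_micro, M_macro, atol=1e-12)


class TestMicroMeanField:
    def test_zero_drive_relaxes_to_half(self):
        # m = 1/2 with rested synapses gives sigma = 0, hence h = 0, g(0) = 1/2
        pat = dm.MemoryPatternSet(N=2, p=1, b=0.0,
                                  parent=np.array([1, -1]),
                                  children=np.array([[1, -1]]))
        params = dm.ModelParams(T=1.0, N=2)
        m2, _, _ = dm.micro_mf_step(np.full(2, 0.5), np.ones(2), np.full(2, 0.1),
                                    pat, params)
        assert np.allclose(m2, 0.5)

    def test_exact_sublattice_reduction(self):
        # sublattice-constant micro trajectory equals the finite-N macro map
        pat = dm.generate_patterns(800, 3, 0.2, seed=42)
        sub = dm.build_sublattices(pat)
        params = dm.ModelParams(T=0.9, tau_R=10, tau_F=2, N=800)
        state = dm.SublatticeState.from_activity(
            np.random.default_rng(7).uniform(0, 1, 8), params
        )
        m = state.m[sub.membership].copy()
        X = state.X[sub.membership].copy()
        U = state.U[sub.membership].copy()
        for _ in range(200):
            m, X, U = dm.micro_mf_step(m, X, U, pat, params)
            state = dm.macro_mf_step(state, sub, params, finite_n=800)
        assert np.abs(m - state.m[sub.membership]).max() < 1e-12
        assert np.abs(X - state.X[sub.membership]).max() < 1e-12
        assert np.abs(U - state.U[sub.membership]).max() < 1e-12


class TestSimulateAndIO:
    def test_constant_trajectory_from_fixed_point(self, spec, seeds):
        params = dm.ModelParams(T=0.8, tau_R=4, tau_F=2)
        fp = dm.solve_fixed_point(seeds["PARA"], spec, params)
        traj = dm.macro_mf_simulate(fp.state, spec, params, 50)
        assert np.abs(traj.m - traj.m[0]).max() < 1e-12

    def test_depression_orbit_is_quasiperiodic(self, spec, seeds):
        # tau_R = 10, T = 0.9: attractor is an invariant circle, not a point
        params = dm.ModelParams(T=0.9, tau_R=10, tau_F=2)
        state0 = dm.SublatticeState.from_activity(seeds["MEM+1"], params)
        traj = dm.macro_mf_simulate(state0, spec, params, 6000)
        tail = traj.M[3000:]
        assert (tail.max(axis=0) - tail.min(axis=0)).max() > 0.1

    def test_trajectory_csv(self, spec, seeds, tmp_path):
        params = dm.ModelParams(T=0.5)
        state0 = dm.SublatticeState.from_activity(seeds["SMIX+"], params)
        traj = dm.macro_mf_simulate(state0, spec, params, 10)
        save_trajectory_csv(traj, tmp_path / "traj.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "traj.csv")
        assert len(df) == 11 and "M1" in df.columns and "m_7" in df.columns

    def test_finite_n_field_includes_self_term(self, spec):
        params = dm.ModelParams(T=0.5)
        state = dm.SublatticeState.from_activity(np.linspace(0.1, 0.9, 8), params)
        h_inf = macro_field(state, spec, params)
        h_fin = macro_field(state, spec, params, finite_n=100)
        sigma = 2 * state.m * state.X * state.U / params.U_se - 1
        assert np.allclose(h_inf - h_fin, (3 / 100) * sigma)
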