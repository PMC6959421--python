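import numpy as np
import pytest

import chondrosim as cs
from chondrosim import (DAY, ModelParameters, ParameterError,
                        ScenarioConfig, fixed_point_iteration,
                        make_initial_state, postprocess_state,
                        run_simulation, scenario_presets)

#: rate overrides that freeze all kinetics at rounding level (the
#: parameter container requires strictly positive rates)
_FROZEN = dict(R_n=1e-30, R_v=1e-30, R_q=1e-30, k_apo=1e-30, k_qui=1e-30,
               k_deg=1e-30, k_g=1e-30, k_GAG=1e-40, beta_qn=1e-30,
               beta_qv=1e-30, beta_vq=1e-30, tau_m=1e30, D_eta=0.0)


def small_cfg(**kwargs):
    base = dict(N=20, dt=3600.0, T_end=2 * DAY, sample_every=2)
    base.update(kwargs)
    return ScenarioConfig(**base)


class TestInitialState:
    def test_seeding_profile_values(self):
        cfg = small_cfg()
        state = make_initial_state(cfg)
        assert state.phi_n[0] == pytest.approx(0.005)
        assert state.phi_v[0] == pytest.approx(0.001)
        assert state.phi_fl[0] == pytest.approx(0.992)
        # at x = L_d the profile has decayed by 1/e
        x = state.mesh.nodes
        i = int(np.argmin(np.abs(x - cfg.L_d)))
        assert state.phi_n[i] == pytest.approx(0.005 * np.exp(-x[i] / cfg.L_d),
                                               rel=1e-12)
        assert np.all(state.c == cfg.params.c0)
        assert np.all(state.u == 0.0) and np.all(state.g_n == 0.0)

    def test_high_density_preset(self):
        cfg = small_cfg(**cs.IC_PRESETS["IC2"])
        state = make_initial_state(cfg)
        assert state.phi_n[0] == pytest.approx(0.05)

    def test_overfull_seeding_rejected(self):
        with pytest.raises(ParameterError):
            small_cfg(A_n=0.6, A_v=0.2, A_q=0.2, A_ECM=0.1).validate()

    def test_initial_state_is_isotropic(self):
        state = make_initial_state(small_cfg())
        assert np.all(state.xi == 1.0) and np.all(state.r == 0.0)


class TestFixedPoint:
    def test_frozen_kinetics_is_a_fixed_point(self):
        """With all rates frozen and no boundary forcing the state is
        already the solution; the sweep terminates immediately."""
        cfg = small_cfg(params=ModelParameters(**_FROZEN), c_ext=5e-6)
        state = make_initial_state(cfg)
        new, iters, converged = fixed_point_iteration(state, cfg)
        assert converged and iters <= 2
        for name in ("phi_n", "phi_v", "phi_q", "phi_ECM", "c"):
            assert np.allclose(getattr(new, name), getattr(state, name),
                               rtol=1e-10, atol=1e-20)

    def test_residual_decreases_and_sweeps_finite(self):
        cfg = small_cfg()
        state = make_initial_state(cfg)
        new, iters, converged = fixed_point_iteration(state, cfg)
        assert converged and 1 <= iters <= cfg.max_inner_iters

    def test_tightening_tolerance_changes_little(self):
        """Halving the fixed-point tolerance moves the day-1 midpoint
        secreting fraction by far less than 0.1%."""
        outs = []
        for tol in (1e-8, 5e-9):
            cfg = small_cfg(T_end=1 * DAY, fixed_point_tol=tol)
            rec = run_simulation(cfg, store_grids=False)
            outs.append(rec.midpoint["phi_v"][-1])
        assert abs(outs[0] - outs[1]) / outs[1] < 1e-3


class TestRunSimulation:
    def test_frozen_kinetics_static_run_is_constant(self):
        cfg = small_cfg(params=ModelParameters(**_FROZEN), c_ext=5e-6)
        rec = run_simulation(cfg, store_grids=False)
        for name in ("phi_n", "phi_v", "phi_q", "phi_ECM", "c"):
            series = rec.midpoint[name]
            assert np.allclose(series, series[0], rtol=1e-9, atol=1e-20)

    def test_closed_kinetics_conserves_each_species(self):
        """Zero production, zero boundary forcing: the domain integral of
        every solid fraction is constant in time."""
        cfg = small_cfg(params=ModelParameters(**_FROZEN), N=30)
        state = make_initial_state(cfg)
        m = state.mesh.lumped_mass()
        before = {k: float(m @ getattr(state, k))
                  for k in ("phi_n", "phi_v", "phi_q", "phi_ECM")}
        for _ in range(10):
            state, _, _ = fixed_point_iteration(state, cfg)
        for k, b in before.items():
            assert float(m @ getattr(state, k)) == pytest.approx(b, rel=1e-8)

    def test_saturation_positivity_and_oxygen_bounds(self):
        cfg = small_cfg(T_end=2 * DAY, c_ext=6.4e-6)
        state = make_initial_state(cfg)
        cap = max(cfg.params.c0, cfg.c_ext)
        for _ in range(cfg.n_steps):
            state, _, _ = fixed_point_iteration(state, cfg)
            total = (state.phi_n + state.phi_v + state.phi_q
                     + state.phi_ECM + state.phi_fl)
            assert np.max(np.abs(total - 1.0)) < 1e-12
            for f in (state.phi_n, state.phi_v, state.phi_q, state.phi_ECM,
                      state.c):
                assert f.min() >= 0.0
            assert state.c.max() <= cap * (1 + 1e-12)

    def test_uniform_culture_tracks_well_mixed_oracle(self):
        """Uniform seeding, no transport forcing: the PDE machinery must
        reduce to the pointwise kinetics.  Oracle: independently coded
        backward-Euler Newton solve of the four pool ODEs."""
        p = ModelParameters(R_n=1e-30, R_v=1e-30, R_q=1e-30)
        cfg = small_cfg(params=p, N=8, dt=3600.0, T_end=30 * DAY,
                        A_n=5e-4, A_v=1e-4, A_q=1e-4, A_ECM=1e-4,
                        c_ext=p.c0)
        state = make_initial_state(cfg)
        for name in ("phi_n", "phi_v", "phi_q", "phi_ECM"):
            f = getattr(state, name)
            f[:] = f[0]          # flatten the seeding profile
        state = postprocess_state(state, p)
        amps = [5e-4, 1e-4, 1e-4, 1e-4]

        # oracle: implicit Euler with Newton on the H_r=0, H_c=1 kinetics
        def Q_of(y):
            n, v, q, e = y
            mono = p.c0 / (p.K_sat + p.c0)
            fl = 1 - y.sum()
            return np.array([
                -n / p.tau_m + n * fl * mono * p.k_g,
                -(p.beta_vq + p.k_apo) * v,
                n / p.tau_m + p.beta_vq * v - p.k_apo * q,
                (v / 5.23598775598e-10) * p.c0 * p.E * p.k_GAG
                * (1 - e / p.phi_ECM_max) - p.k_deg * e,
            ])

        y = np.array(amps)
        eye = np.eye(4)
        for _ in range(cfg.n_steps):
            z = y.copy()
            for _ in range(30):
                F = z - y - cfg.dt * Q_of(z)
                J = np.empty((4, 4))
                for j in range(4):
                    dz = z.copy()
                    step = max(1e-12, 1e-7 * abs(z[j]))
                    dz[j] += step
                    J[:, j] = (dz - y - cfg.dt * Q_of(dz) - F) / step
                delta = np.linalg.solve(J, -F)
                z = z + delta
                if np.max(np.abs(delta)) < 1e-20:
                    break
            y = z

        for _ in range(cfg.n_steps):
            state, _, conv = fixed_point_iteration(state, cfg)
            assert conv
        mid = state.mesh.N // 2
        got = np.array([state.phi_n[mid], state.phi_v[mid],
                        state.phi_q[mid], state.phi_ECM[mid]])
        assert np.all(np.abs(got - y) / np.abs(y) < 1e-3)

    def test_temporal_self_convergence_first_order(self):
        """Backward Euler: the dt -> dt/2 difference shrinks by about two."""
        vals = []
        for dt in (7200.0, 3600.0, 1800.0):
            cfg = small_cfg(N=16, dt=dt, T_end=5 * DAY, sample_every=10**6)
            rec = run_simulation(cfg, store_grids=False)
            vals.append(rec.midpoint["phi_v"][-1])
        d1 = abs(vals[0] - vals[1])
        d2 = abs(vals[1] - vals[2])
        assert d1 / d2 == pytest.approx(2.0, rel=0.5)


class TestPostprocess:
    def test_fluid_closure_and_relaxed_isotropy(self):
        cfg = small_cfg()
        state = make_initial_state(cfg)
        assert np.allclose(state.phi_fl + state.phi_n + state.phi_v
                           + state.phi_q + state.phi_ECM, 1.0)
        assert np.all(state.xi == 1.0)

    def test_overfull_fraction_rejected(self):
        cfg = small_cfg()
        state = make_initial_state(cfg)
        state.phi_n[3] = 1.5
        with pytest.raises(ParameterError):
            postprocess_state(state, cfg.params)

    def test_perfusion_traction_turns_state_anisotropic(self):
        cfg = small_cfg(T_b=1.0, V_b=-5e-3, dt=600.0)
        state = make_initial_state(cfg)
        state, _, _ = fixed_point_iteration(state, cfg)
        assert np.all(state.xi == 0.0)
        assert np.all(state.r > cs.derived_parameters(cfg.params).r_bar)


class TestPresets:
    def test_sixteen_scenarios(self):
        presets = scenario_presets()
        assert len(presets) == 16
        assert "static-IC1-kg1-csat" in presets
        assert "perfused-IC2-kg2-cthr" in presets

    def test_static_presets_are_unforced(self):
        cfg = scenario_presets()["static-IC1-kg1-csat"]
        assert cfg.T_b == 0.0 and cfg.V_b == 0.0
        assert cfg.params.k_g == 1e-7 and cfg.c_ext == 6.4e-6

    def test_perfused_presets_drive_inflow(self):
        cfg = scenario_presets()["perfused-IC1-kg2-cthr"]
        assert cfg.T_b == 1.0          # 100 mPa in CGS
        assert cfg.V_b == -5e-3        # inlet flow into the construct
        assert cfg.params.k_g == 1e-5 and cfg.c_ext == 1.6e-6
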