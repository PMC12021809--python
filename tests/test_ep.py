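"""Monodomain solver, Courtemanche cell model, CV calibration, spirals."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fibrotwin import courtemanche as crn
from fibrotwin import ep, features
from fibrotwin.remodeling import (BASELINE_SCALING, ionic_scaling_fields,
                                  ionic_scaling_for)


def make_sheet(n=8, iir=0.5, conducting=None, upsample=1):
    from fibrotwin.ep import TissueParams, TissueSheet
    from fibrotwin.remodeling import conductivity_from_iir
    iir_map = np.full((n, n), iir)
    cond = np.ones((n, n), bool) if conducting is None else conducting
    return TissueSheet("LA", TissueParams(
        conductivity_from_iir(iir_map), cond, ionic_scaling_fields(iir_map)))


class TestCellModel:
    def test_resting_state_physiological(self):
        s = crn.initial_state(3)
        assert -85 <= s[0, 0] <= -75
        assert np.all(s[1:16] >= 0) and np.all(s[1:16] <= 1)
        assert np.all(s[16:] > 0)

    def test_action_potential_matches_ode_oracle(self):
        """Rush-Larsen trajectory vs an independent stiff ODE integration of
        the same right-hand side (baseline scalings, one stimulated beat)."""
        scal = BASELINE_SCALING
        stim = lambda t: 40.0 if 5.0 <= t < 7.0 else 0.0
        sol = solve_ivp(crn.rhs_flat, (0, 120), crn.INITIAL_STATE,
                        args=(scal, stim), method="LSODA", rtol=1e-7,
                        atol=1e-9, dense_output=True, max_step=1.0)
        state = crn.initial_state(1)
        one = np.ones(1)
        mults = (scal.g_Na * one, scal.g_K1 * one, scal.g_to * one,
                 scal.g_Kur * one, scal.g_CaL * one)
        dt = 0.005
        errs, v_rl = [], []
        for step in range(int(120 / dt)):
            t = step * dt
            crn.step_rush_larsen(state, dt, *mults, one * stim(t))
            if step % 200 == 0 and t > 10:
                errs.append(abs(state[0, 0] - sol.sol(t + dt)[0]))
                v_rl.append(state[0, 0])
        v_rl = np.array(v_rl)
        assert max(v_rl) > 0            # overshoot above 0 mV
        assert np.median(errs) < 2.0    # mV, integrator-level agreement
        # exclude upstroke frames where a sub-ms shift dominates the error
        assert np.percentile(errs, 80) < 5.0

    def test_quiescence_without_stimulus(self):
        # from the settled rest of the modified model, not the published ICs
        state = crn.equilibrated_state(BASELINE_SCALING)[:, None].copy()
        one, zero = np.ones(1), np.zeros(1)
        scal = BASELINE_SCALING
        mults = (scal.g_Na * one, scal.g_K1 * one, scal.g_to * one,
                 scal.g_Kur * one, scal.g_CaL * one)
        v0 = state[0, 0]
        assert -85 <= v0 <= -75
        for _ in range(int(1000 / 0.05)):
            crn.step_rush_larsen(state, 0.05, *mults, zero)
        assert abs(state[0, 0] - v0) < 1.0


class TestMonodomain:
    def test_pure_diffusion_conserves_mean(self, rng):
        sheet = make_sheet(12)
        init = crn.initial_state(144).reshape(21, 12, 12).copy()
        init[0] = rng.uniform(-80, 20, (12, 12))
        res = ep.run_monodomain([sheet], 100.0, dt_ms=0.05,
                                init_states=[init], frozen_reaction=True,
                                bridges=[])
        m0 = res.voltages[0][0].mean()
        m1 = res.voltages[0][-1].mean()
        assert abs(m1 - m0) < 1e-6

    def test_nonconducting_domain_never_activates(self):
        sheet = make_sheet(8, conducting=np.zeros((8, 8), bool))
        stim = ep.Stimulus([np.ones((8, 8), bool)], 1.0, 2.0, amplitude=60.0)
        res = ep.run_monodomain([sheet], 50.0, stimuli=[stim], bridges=[])
        assert res.voltages[0].max() < -40.0
        assert np.all(np.isnan(res.last_activation[0]))

    def test_resting_tissue_numerical_quiescence(self):
        sheet = make_sheet(6)
        scal = crn.equilibrated_state(ionic_scaling_for(0.5))
        init = np.repeat(scal[:, None], 36, axis=1).reshape(21, 6, 6)
        res = ep.run_monodomain([sheet], 1000.0, dt_ms=0.05,
                                init_states=[init], bridges=[])
        drift = np.abs(res.voltages[0][-1] - res.voltages[0][0]).max()
        assert drift < 1.0

    def test_determinism(self):
        sheet = make_sheet(6)
        stim = ep.Stimulus([np.ones((6, 6), bool)], 1.0, 2.0)
        a = ep.run_monodomain([sheet], 30.0, stimuli=[stim], bridges=[])
        b = ep.run_monodomain([make_sheet(6)], 30.0, stimuli=[stim], bridges=[])
        np.testing.assert_array_equal(a.voltages[0], b.voltages[0])

    def test_instability_reported_with_step(self):
        sheet = make_sheet(6)
        init = crn.initial_state(36).reshape(21, 6, 6).copy()
        init[0] = 1e4  # blatantly unphysical start
        with pytest.raises(ep.SimulationInstabilityError, match="step"):
            ep.run_monodomain([sheet], 5.0, init_states=[init], bridges=[])

    def test_hdf5_roundtrip(self, tmp_path):
        sheet = make_sheet(6)
        res = ep.run_monodomain([sheet], 10.0, bridges=[])
        path = tmp_path / "sim.h5"
        res.to_hdf5(path, seed=3)
        back = ep.SimulationResult.from_hdf5(path)
        np.testing.assert_allclose(back.voltages[0], res.voltages[0])
        assert back.duration_ms == res.duration_ms


class TestConductionVelocity:
    def test_anchor_calibration(self):
        cv = ep.measure_cv(0.40)
        assert cv == pytest.approx(0.81, rel=0.015)

    @pytest.mark.parametrize("sigma,target", [(0.31, 0.74), (0.28, 0.71),
                                              (0.19, 0.58)])
    def test_bins_within_ten_percent(self, sigma, target):
        assert ep.measure_cv(sigma) == pytest.approx(target, rel=0.10)

    def test_monotone_in_conductivity(self):
        cvs = [ep.measure_cv(s) for s in (0.19, 0.28, 0.31, 0.40)]
        assert cvs == sorted(cvs)

    def test_dt_convergence(self):
        a = ep.measure_cv(0.40, dt_ms=0.02)
        b = ep.measure_cv(0.40, dt_ms=0.01)
        assert abs(a - b) / b < 0.02

    def test_sqrt_scaling_with_conductivity(self):
        # on a fine strand CV ~ sqrt(sigma): quartering sigma halves CV
        kw = dict(spacing_mm=0.1, n_nodes=250)
        ratio = ep.measure_cv(0.40, **kw) / ep.measure_cv(0.10, **kw)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_block_reported(self):
        with pytest.raises(ep.ConductionBlockError):
            ep.measure_cv(0.40, chi=1e5)  # absurdly low coupling

    def test_calibrate_chi_hits_anchor(self):
        chi = ep.calibrate_chi(chi0=1.0)
        assert ep.measure_cv(0.40, chi=chi) == pytest.approx(0.81, rel=0.01)


class TestSpirals:
    def test_phase_field_singularity_counts(self):
        phi1 = ep.spiral_phase_field((48, 48), [(24.0, 24.0)])
        ps1 = features.find_phase_singularities(phi1)
        assert len(ps1) == 1
        phi = ep.spiral_phase_field((48, 48), [(12.0, 12.0), (36.0, 36.0)])
        assert len(features.find_phase_singularities(phi)) == 2

    def test_four_spirals_two_per_sheet(self):
        sheets = [make_sheet(48), make_sheet(48)]
        traj = ep.limit_cycle_trajectory(cycle_length_ms=250.0)
        states = ep.initiate_spirals(sheets, 4, seed=0, trajectory=traj)
        assert len(states) == 2
        for st in states:
            assert st.shape == (21, 48, 48)
            assert np.all(np.isfinite(st))

    def test_seeded_core_placement(self):
        sheets = [make_sheet(24), make_sheet(24)]
        traj = ep.limit_cycle_trajectory(cycle_length_ms=250.0)
        a = ep.initiate_spirals(sheets, 4, seed=5, trajectory=traj)
        b = ep.initiate_spirals(sheets, 4, seed=5, trajectory=traj)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_core_outside_grid_rejected(self):
        sheets = [make_sheet(16)]
        traj = np.tile(crn.INITIAL_STATE[:, None], (1, 10))
        with pytest.raises(ValueError):
            ep.initiate_spirals(sheets, 1, seed=0, trajectory=traj,
                                cores=[[(50.0, 5.0)]])


class TestSustainability:
    @staticmethod
    def fake_result(last_act_ms, duration=1000.0):
        la = np.full((4, 4), np.nan)
        la[0, 0] = last_act_ms
        return ep.SimulationResult(
            voltages=[np.zeros((2, 4, 4), np.float32)],
            last_activation=[la], conducting=[np.ones((4, 4), bool)],
            duration_ms=duration, dt_ms=0.02, downsample_ms=1.0,
            sheet_names=["LA"])

    def test_late_activity_sustained(self):
        assert ep.is_sustained(self.fake_result(800.0))

    def test_early_silence_not_sustained(self):
        assert not ep.is_sustained(self.fake_result(500.0))

    def test_no_activity_not_sustained(self):
        res = self.fake_result(0.0)
        res.last_activation[0][:] = np.nan
        assert not ep.is_sustained(res)

    def test_zero_duration_rejected(self):
        res = self.fake_result(0.0)
        res.duration_ms = 0.0
        with pytest.raises(ValueError):
            ep.is_sustained(res)
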