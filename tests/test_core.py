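"""Unit tests for the reaction/flux right-hand sides."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import actinwaves as aw
from actinwaves.core import (bulk_reaction_rates, conservation_corrections,
                             elongation_speeds, membrane_layer_rates,
                             short_filament_closure, total_barbed_ends)
from actinwaves.state import BarbedEndDensity


class TestElongationSpeeds:
    def test_zero_membrane_gactin_gives_pure_shrinkage(self, params):
        vc, vf = elongation_speeds(np.zeros(4), params)
        assert np.all(vc == 0.0)
        assert np.allclose(vf, -params.v_depoly)

    def test_treadmilling_balance_point(self, params):
        g_star = params.v_depoly / params.v_poly
        _, vf = elongation_speeds(np.full(3, g_star), params)
        assert np.allclose(vf, 0.0, atol=1e-14)

    def test_capped_grow_while_free_shrink(self, params):
        # the wave-back regime: protected branches lengthen, exposed ones erode
        g_m = 0.5 * params.v_depoly / params.v_poly
        vc, vf = elongation_speeds(np.array([g_m]), params)
        assert vc[0] > 0.0 > vf[0]

    def test_negative_input_rejected(self, params):
        with pytest.raises(ValueError):
            elongation_speeds(np.array([-0.1]), params)


class TestBulkReactionRates:
    def test_zero_state_gives_zero_rates(self, small_grid, params):
        s = aw.CytosolState.zeros(small_grid)
        rates = bulk_reaction_rates(s, params)
        for v in rates.values():
            assert np.all(v == 0.0)

    def test_pointed_end_types_conserved_pointwise(self, random_state, params):
        s, _ = random_state
        rates = bulk_reaction_rates(s, params)
        np.testing.assert_allclose(rates["p"] + rates["r"] + rates["c"], 0.0,
                                   atol=1e-14)

    def test_coronin_binding_mass_action_arithmetic(self, small_grid):
        # r = 2, cor = 3, k_cor = 0.5: conversion flux = 3.0 per unit time
        p = aw.ModelParams().replace(k_cor=0.5, k_debranch=0.0,
                                     k_rac_spont=0.0, k_rac_deact=0.0)
        s = aw.CytosolState.zeros(small_grid)
        s.r[:] = 2.0
        s.cor[:] = 3.0
        rates = bulk_reaction_rates(s, p)
        np.testing.assert_allclose(rates["c"], 3.0)
        np.testing.assert_allclose(rates["arp"], 3.0)
        np.testing.assert_allclose(rates["cor"], -3.0)
        np.testing.assert_allclose(rates["r"], -3.0)

    def test_matches_discrete_oracle_single_reaction(self):
        # same coronin-binding configuration evaluated by the monomer model
        from actinwaves.discrete import DiscreteState, step_discrete
        p = aw.ModelParams().replace(
            k_cor=0.5, k_debranch=0.0, k_rac_spont=0.0, k_rac_deact=0.0,
            v_poly=0.0, v_depoly=0.0, k_poly=0.0, k_depoly=0.0, k_dim=0.0,
            k_branch=0.0, k_wasp_act=0.0, k_gm_on=0.0, k_gm_off=0.0,
            k_rac_act=0.0, k_arp_on=0.0, k_gact_on=0.0,
            D_g=0.0, D_arp=0.0, D_cor=0.0, D_rac=0.0, delta=0.1)
        ds = DiscreteState.zeros(10, p.delta)
        ds.R[5] = 2.0 * p.delta          # concentration 2 in segment 5
        ds.Cor[5] = 3.0 * p.delta        # concentration 3
        dt = 1e-4
        ds2 = step_discrete(ds, dt, p)
        # flux k_cor * cor * r = 3.0 concentration/time
        np.testing.assert_allclose((ds2.C[5] - ds.C[5]) / dt / p.delta, 3.0,
                                   rtol=1e-9)

    def test_depoly_source_scale(self, small_grid, params):
        s = aw.CytosolState.zeros(small_grid)
        s.p[:] = 1.0
        rates = bulk_reaction_rates(s, params)
        np.testing.assert_allclose(rates["g"], params.v_depoly / params.delta)

    def test_shape_mismatch_rejected(self, small_grid, params):
        s = aw.CytosolState.zeros(small_grid)
        s.g = np.zeros((2, 2))
        with pytest.raises(ValueError):
            bulk_reaction_rates(s, params)


def _traces(grid, **values):
    out = {n: np.zeros(grid.nx) for n in ("g", "arp", "cor", "rac", "rac_star")}
    for k, v in values.items():
        out[k][:] = v
    return out


class TestMembraneLayerRates:
    def test_no_barbed_ends_no_activation_no_branching(self, small_grid, params):
        mem = aw.MembraneState.resting(small_grid, params)
        mem.WAG[:] = 0.1
        mem.W[:] -= 0.1
        B = BarbedEndDensity(B=np.zeros(small_grid.nx))
        tr = _traces(small_grid, rac=1.0)
        rates, flux = membrane_layer_rates(mem, tr, B, params)
        assert np.all(flux["rac"] == 0.0)
        assert np.all(flux["rac_star"] == 0.0)
        assert np.all(rates["s_r1"] == 0.0)

    def test_wasp_cycle_conserves_total(self, small_grid, params, rng):
        mem = aw.MembraneState.resting(small_grid, params)
        mem.W[:] = 0.1
        mem.W_star[:] = 0.2
        mem.WA[:] = 0.2
        mem.WAG[:] = params.W_total - 0.5
        B = BarbedEndDensity(B=rng.random(small_grid.nx))
        tr = _traces(small_grid, g=5.0, arp=0.5, rac=1.0, rac_star=0.5)
        rates, _ = membrane_layer_rates(mem, tr, B, params)
        total = rates["W"] + rates["W_star"] + rates["WA"] + rates["WAG"]
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_cycle_drains_to_inactive_wasp(self, small_grid, params):
        # no activated Rac, Arp2/3 or membrane G-actin: every rate pushes
        # the cycle back toward W
        mem = aw.MembraneState.resting(small_grid, params)
        mem.W[:] = 0.0
        mem.W_star[:] = 0.2
        mem.WA[:] = 0.2
        mem.WAG[:] = 0.2
        B = BarbedEndDensity(B=np.zeros(small_grid.nx))
        tr = _traces(small_grid)
        rates, _ = membrane_layer_rates(mem, tr, B, params)
        assert np.all(rates["W"] > 0.0)
        assert np.all(rates["WAG"] <= 0.0)

    def test_pten_mask_zeroes_rac_activation(self, small_grid, params):
        mem = aw.MembraneState.resting(small_grid, params)
        B = BarbedEndDensity(B=np.ones(small_grid.nx))
        tr = _traces(small_grid, rac=1.0)
        mask = np.zeros(small_grid.nx, dtype=bool)
        mask[:4] = True
        _, flux = membrane_layer_rates(mem, tr, B, params, pten_mask=mask)
        assert np.all(flux["rac"][:4] == 0.0)
        assert np.all(flux["rac"][4:] < 0.0)

    def test_mask_length_mismatch_rejected(self, small_grid, params):
        mem = aw.MembraneState.resting(small_grid, params)
        B = BarbedEndDensity(B=np.zeros(small_grid.nx))
        with pytest.raises(ValueError):
            membrane_layer_rates(mem, _traces(small_grid), B, params,
                                 pten_mask=np.zeros(3, dtype=bool))

    def test_negative_trace_rejected(self, small_grid, params):
        mem = aw.MembraneState.resting(small_grid, params)
        B = BarbedEndDensity(B=np.zeros(small_grid.nx))
        tr = _traces(small_grid, g=-1.0)
        with pytest.raises(ValueError):
            membrane_layer_rates(mem, tr, B, params)


class TestShortFilamentClosure:
    def test_all_zero_state(self, small_grid, params):
        mem = aw.MembraneState.resting(small_grid, params)
        vc, vf = elongation_speeds(mem.g_m, params)
        rates, fluxes, aux = short_filament_closure(mem, vc, vf, params)
        for v in list(rates.values()) + list(fluxes.values()):
            assert np.all(v == 0.0)

    def test_dimerization_only_growth_rate(self, small_grid):
        # with transport frozen, d s_p2/dt equals the dimerization source
        # (fed through membrane_layer_rates); the closure adds no sink
        p = aw.ModelParams().replace(v_poly=0.0, v_depoly=0.0, k_poly=0.0,
                                     k_depoly=0.0)
        mem = aw.MembraneState.resting(small_grid, p)
        mem.g_m[:] = 2.0
        rates, _, _ = short_filament_closure(mem, np.zeros(small_grid.nx),
                                             np.zeros(small_grid.nx), p)
        assert np.all(rates["s_p2"] == 0.0)
        mrates, _ = membrane_layer_rates(
            mem, _traces(small_grid), BarbedEndDensity(B=np.zeros(small_grid.nx)), p)
        np.testing.assert_allclose(mrates["s_p2"], p.k_dim * 4.0)

    def test_pseudo_steady_pool_matches_ode_stationary_state(self, params):
        # brute-force oracle: integrate the un-eliminated length-3 ODE with
        # frozen transport rates to stationarity and compare with the
        # algebraic closure value
        grid = aw.GridSpec(Lx=1.0, Lz=2.0, nx=1, nz=10, dt=0.01)
        mem = aw.MembraneState.resting(grid, params)
        mem.s_p2[:] = 0.7
        g_m = np.array([1.3])
        vc, vf = elongation_speeds(g_m, params)
        mem.g_m[:] = g_m
        p_bottom = np.array([0.4])
        _, _, aux = short_filament_closure(mem, vc, vf, params,
                                           p_bottom=p_bottom)
        lam = float(aux["lam"][0])
        mu = float(aux["mu"][0])
        J = float(aux["J_p"][0])

        def rhs(t, y):
            return [lam * 0.7 + J - (lam + mu) * y[0]]

        sol = solve_ivp(rhs, [0.0, 50.0 / (lam + mu)], [0.0], rtol=1e-10,
                        atol=1e-14)
        assert abs(sol.y[0, -1] - aux["p3"][0]) / aux["p3"][0] < 1e-6

    def test_capped_length3_pools_equal_length2(self, small_grid, params, rng):
        mem = aw.MembraneState.resting(small_grid, params)
        mem.s_r2[:] = rng.random(small_grid.nx)
        mem.s_c2[:] = rng.random(small_grid.nx)
        mem.g_m[:] = 1.0
        vc, vf = elongation_speeds(mem.g_m, params)
        _, _, aux = short_filament_closure(mem, vc, vf, params)
        np.testing.assert_allclose(aux["r3"], mem.s_r2)
        np.testing.assert_allclose(aux["c3"], mem.s_c2)


class TestTotalBarbedEnds:
    def test_empty_network(self, small_grid, params):
        s = aw.CytosolState.zeros(small_grid)
        m = aw.MembraneState.resting(small_grid, params)
        B = total_barbed_ends(s, m, small_grid, params)
        assert np.all(B.B == 0.0)

    def test_single_cell_column_integral(self, small_grid, params):
        s = aw.CytosolState.zeros(small_grid)
        m = aw.MembraneState.resting(small_grid, params)
        # column integral of p equivalent to 5 ends per unit area
        s.p[3, 7] = 5.0 / small_grid.dz
        B = total_barbed_ends(s, m, small_grid, params)
        assert B.B[3] == pytest.approx(5.0)
        assert np.all(B.B[:3] == 0.0)

    def test_random_state_matches_brute_force(self, random_state, small_grid,
                                              params):
        s, m = random_state
        B = total_barbed_ends(s, m, small_grid, params)
        vc, vf = elongation_speeds(m.g_m, params)
        _, _, aux = short_filament_closure(m, vc, vf, params,
                                           p_bottom=s.p[:, 0],
                                           cor0=s.cor[:, 0])
        brute = np.zeros(small_grid.nx)
        for i in range(small_grid.nx):
            brute[i] = (sum(s.p[i]) + sum(s.r[i]) + sum(s.c[i])) * small_grid.dz
            for pool in ("s_p1", "s_p2", "s_r1", "s_r2", "s_c1", "s_c2"):
                brute[i] += getattr(m, pool)[i]
            brute[i] += aux["p3"][i] + aux["r3"][i] + aux["c3"][i]
        np.testing.assert_allclose(B.B, brute, rtol=1e-12)


class TestConservationCorrections:
    def test_zero_when_disabled_and_empty(self, small_grid):
        # no transport speeds and empty pools: corrections vanish
        p = aw.ModelParams().replace(v_poly=0.0, v_depoly=0.0, k_poly=0.0,
                                     k_depoly=0.0)
        s = aw.CytosolState.zeros(small_grid)
        m = aw.MembraneState.resting(small_grid, p)
        out = conservation_corrections(s, m, small_grid, p)
        np.testing.assert_allclose(out["g_flux"], 0.0, atol=1e-15)

    def test_transition_term_sign(self, small_grid, params):
        # each filament entering the continuum at the bottom-cell centre
        # represents z0/delta subunits but is paid for with 4: the correction
        # must remove the difference from G-actin
        s = aw.CytosolState.zeros(small_grid)
        m = aw.MembraneState.resting(small_grid, params)
        m.g_m[:] = 1.0
        m.s_p2[:] = 0.5
        out = conservation_corrections(s, m, small_grid, params)
        z0 = small_grid.dz / 2.0
        assert z0 / params.delta > 4.0      # resolution regime of the model
        assert np.all(out["transition"] < 0.0)

    def test_closed_run_budget_drift_is_roundoff(self):
        # the audit-level validation of the corrections: a full stepped run
        # in a closed domain conserves actin to accumulation round-off
        cfg = aw.SimulationConfig(
            params=aw.ModelParams(),
            grid=aw.GridSpec(Lx=4.0, Lz=2.0, nx=16, nz=24, dt=0.02),
            stimuli=[aw.StimulusProtocol(x0=1.0, x1=3.0, start=0.5,
                                         duration=5.0, fold=300.0)],
            t_end=20.0, output_every=20.0)
        traj = aw.run(cfg)
        a0 = aw.conservation_audit(traj.states[0], traj.membranes[0],
                                   cfg.grid, cfg.params)
        a1 = aw.conservation_audit(traj.states[-1], traj.membranes[-1],
                                   cfg.grid, cfg.params)
        assert abs(a1["actin"] - a0["actin"]) / a0["actin"] < 1e-8
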