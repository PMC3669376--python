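"""Transport/diffusion kernels, the composed step, and run-level contracts."""

import numpy as np
import pytest

import actinwaves as aw
from actinwaves.engine import (PTENRegion, SolverError, StepSizeError,
                               Simulator, StimulusProtocol, advect_filaments,
                               diffuse_cytosol, run, stabilizing_diffusion)


@pytest.fixture()
def grid():
    return aw.GridSpec(Lx=2.0, Lz=4.0, nx=4, nz=80, dt=0.01)


class TestAdvection:
    def test_zero_speed_leaves_field_unchanged(self, grid, rng):
        f = rng.random((grid.nx, grid.nz))
        out, _ = advect_filaments(f, np.zeros(grid.nx), 0.01, grid)
        np.testing.assert_array_equal(out, f)

    def test_periodic_square_pulse_centroid_and_monotonicity(self, grid):
        f = np.zeros((grid.nx, grid.nz))
        f[:, 10:20] = 1.0
        v = np.full(grid.nx, 1.0)
        dt = 0.02
        steps = 50
        out = f
        for _ in range(steps):
            out, _ = advect_filaments(out, v, dt, grid, periodic=True)
        z = grid.z_centers
        c0 = (z * f[0]).sum() / f[0].sum()
        c1 = (z * out[0]).sum() / out[0].sum()
        assert c1 - c0 == pytest.approx(v[0] * dt * steps, abs=grid.dz)
        # monotone scheme: no new extrema
        assert out.max() <= f.max() + 1e-12
        assert out.min() >= f.min() - 1e-12

    def test_mass_conserved_with_closed_faces(self, grid, rng):
        f = rng.random((grid.nx, grid.nz))
        v = rng.uniform(-1.0, 1.0, grid.nx)
        out, _ = advect_filaments(f, v, 0.01, grid)
        np.testing.assert_allclose(out.sum(axis=1), f.sum(axis=1), rtol=1e-13)

    def test_cfl_violation_raises(self, grid):
        f = np.zeros((grid.nx, grid.nz))
        with pytest.raises(StepSizeError):
            advect_filaments(f, np.full(grid.nx, 100.0), 1.0, grid)

    def test_stabilizing_diffusion_preserves_column_mass(self, grid, rng):
        f = rng.random((grid.nx, grid.nz))
        nu = np.full(grid.nx, 1e-3)
        out = stabilizing_diffusion(f, nu, 0.01, grid)
        np.testing.assert_allclose(out.sum(axis=1), f.sum(axis=1), rtol=1e-13)


class TestDiffusion:
    def test_uniform_field_unchanged(self, grid):
        f = np.full((grid.nx, grid.nz), 3.7)
        out = diffuse_cytosol(f, 2.0, 0.05, grid)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_point_release_variance_grows_at_2Dt(self):
        g = aw.GridSpec(Lx=12.0, Lz=12.0, nx=96, nz=96, dt=0.01)
        f = np.zeros((g.nx, g.nz))
        f[48, 48] = 1.0 / (g.dx * g.dz)
        D, dt, steps = 1.0, 0.005, 80
        out = f
        for _ in range(steps):
            out = diffuse_cytosol(out, D, dt, g, _cache={})
        z = g.z_centers - g.z_centers[48]
        mass = out.sum() * g.dx * g.dz
        var_z = (out.sum(axis=0) * g.dx * z ** 2).sum() * g.dz / mass
        expect = 2.0 * D * dt * steps + g.dz ** 2 / 12.0
        assert var_z == pytest.approx(expect, rel=0.02)

    def test_boundary_flux_changes_mass_exactly(self, grid):
        f = np.ones((grid.nx, grid.nz))
        flux = np.full(grid.nx, 0.3)
        dt = 0.05
        out = diffuse_cytosol(f, 1.5, dt, grid, boundary_flux=flux)
        gained = (out.sum() - f.sum()) * grid.dz
        np.testing.assert_allclose(gained, flux.sum() * dt, rtol=1e-12)


class TestProtocols:
    def test_stimulus_interval_validation(self):
        with pytest.raises(ValueError):
            StimulusProtocol(x0=2.0, x1=1.0)
        with pytest.raises(ValueError):
            StimulusProtocol(x0=0.0, x1=1.0, fold=0.5)

    def test_pten_region_translation_with_delay(self):
        reg = PTENRegion(x0=5.0, x1=8.0, onset=10.0, speed=-0.1,
                         move_start=20.0)
        assert reg.interval(5.0) is None
        assert reg.interval(15.0) == (5.0, 8.0)
        a, b = reg.interval(30.0)
        assert a == pytest.approx(4.0)
        assert b == pytest.approx(7.0)

    def test_mask_snaps_to_cells(self):
        cfg = aw.SimulationConfig(grid=aw.GridSpec(Lx=10.0, Lz=2.0, nx=10,
                                                   nz=8, dt=0.01))
        cfg.pten_regions = [PTENRegion(x0=2.0, x1=5.0)]
        sim = Simulator(cfg)
        mask = sim.pten_mask(0.0)
        assert list(np.flatnonzero(mask)) == [2, 3, 4]


class TestStep:
    def test_rest_state_without_stimulus_stays_at_rest(self):
        cfg = aw.SimulationConfig(grid=aw.GridSpec(Lx=4.0, Lz=2.0, nx=16,
                                                   nz=20, dt=0.02),
                                  t_end=2.0, output_every=1.0)
        sim = Simulator(cfg)
        state, mem = sim.initial()
        # zero everything (true zero state is an exact fixed point)
        for _, f in state.items():
            f[:] = 0.0
        for name, f in mem.items():
            f[:] = 0.0 if name != "W" else cfg.params.W_total
        # dimerization needs g_m; with everything zero nothing moves
        for i in range(20):
            state, mem = sim.step(state, mem, i * cfg.grid.dt)
        for name, f in state.items():
            assert np.all(f == 0.0), name

    def test_mirror_symmetric_config_stays_symmetric(self):
        grid = aw.GridSpec(Lx=8.0, Lz=2.0, nx=32, nz=20, dt=0.02)
        cfg = aw.SimulationConfig(
            grid=grid, t_end=6.0, output_every=6.0,
            stimuli=[StimulusProtocol(x0=3.0, x1=5.0, start=0.2, duration=5.0,
                                      fold=300.0)])
        traj = run(cfg)
        st = traj.states[-1]
        for name, f in st.items():
            np.testing.assert_allclose(f, f[::-1], rtol=1e-9, atol=1e-12,
                                       err_msg=name)

    def test_halving_dt_changes_result_mildly(self):
        # first-order-in-time self-convergence of the split scheme
        def final_tirf(dt):
            grid = aw.GridSpec(Lx=6.0, Lz=2.5, nx=24, nz=24, dt=dt)
            cfg = aw.SimulationConfig(
                grid=grid, t_end=30.0, output_every=30.0,
                stimuli=[StimulusProtocol(x0=2.0, x1=4.0, start=1.0,
                                          duration=10.0, fold=400.0)])
            traj = run(cfg)
            F = aw.factin_field(traj.states[-1], grid, cfg.params.delta)
            return aw.tirf_intensity(F, 0.2, grid)

        a = final_tirf(0.04)
        b = final_tirf(0.02)
        denom = max(np.abs(b).max(), 1e-12)
        assert np.abs(a - b).max() / denom < 0.05

    def test_nan_state_raises_solver_error(self):
        cfg = aw.SimulationConfig(grid=aw.GridSpec(Lx=2.0, Lz=2.0, nx=8,
                                                   nz=10, dt=0.02))
        sim = Simulator(cfg)
        state, mem = sim.initial()
        state.g[0, 0] = np.nan
        with pytest.raises(SolverError):
            sim.step(state, mem, 0.0)


class TestRun:
    def test_snapshot_count_matches_cadence(self):
        cfg = aw.SimulationConfig(grid=aw.GridSpec(Lx=2.0, Lz=2.0, nx=8,
                                                   nz=10, dt=0.05),
                                  t_end=1.0, output_every=0.5)
        traj = run(cfg)
        np.testing.assert_allclose(traj.times, [0.0, 0.5, 1.0])

    def test_two_runs_are_bitwise_identical(self):
        cfg = aw.SimulationConfig(
            grid=aw.GridSpec(Lx=4.0, Lz=2.0, nx=16, nz=16, dt=0.02),
            t_end=3.0, output_every=1.0,
            stimuli=[StimulusProtocol(x0=1.0, x1=3.0, start=0.1,
                                      duration=2.0, fold=200.0)])
        t1 = run(cfg)
        t2 = run(cfg)
        for s1, s2 in zip(t1.states, t2.states):
            for (n, f1), (_, f2) in zip(s1.items(), s2.items()):
                np.testing.assert_array_equal(f1, f2, err_msg=n)
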