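"""D2Q9 TRT flow solver and the incompressible Stokes channel driver."""

import numpy as np
import pytest

from gutmix.channel_flow import ChannelStokesFlow
from gutmix.lbm_flow import (
    SimulationConfig,
    build_lattice,
    inlet_profile,
    macroscopic_fields,
    run_to_steady,
    step_flow,
)
from gutmix.tracer_lbm import _init_equilibrium

from .oracles import lubrication_profile, stokes_layer_profile


@pytest.fixture(scope="module")
def steady_default():
    """Default 500x10 channel driven to steady state from the developed
    profile (module-scoped: several tests read it)."""
    cfg = SimulationConfig()
    state = build_lattice(cfg)
    _init_equilibrium(state, np.broadcast_to(
        state._ux_in[:, None], (cfg.ny + 1, cfg.nx + 1)))
    run_to_steady(state, 0.0, tol=1e-9)
    return cfg, state, macroscopic_fields(state)


class TestConfig:
    def test_mean_velocity_from_flow_rate(self):
        # Q/(pi R^2) for 0.16 mL/min through a 4 mm lumen
        cfg = SimulationConfig()
        assert cfg.mean_velocity == pytest.approx(2.122e-4, rel=1e-3)
        assert cfg.reynolds_number() < 1.0

    def test_unstable_dt_rejected_with_range(self):
        with pytest.raises(ValueError, match="admissible"):
            build_lattice(SimulationConfig(dt=1.0))

    def test_non_square_lattice_rejected(self):
        with pytest.raises(ValueError, match="square"):
            SimulationConfig(nx=400, ny=10)

    def test_unit_map_round_trip(self):
        um = build_lattice(SimulationConfig()).unit_map
        u = 2.12e-4
        assert um.velocity_to_physical(um.velocity_to_lattice(u)) == \
            pytest.approx(u, rel=1e-14)

    def test_inlet_profile_shape(self):
        cfg = SimulationConfig()
        u = inlet_profile(cfg)
        assert u[-1] == 0.0
        assert u[0] == pytest.approx(1.5 * cfg.mean_velocity, rel=0.01)
        # discrete flux equals U * half-width by construction
        assert np.trapezoid(u, dx=cfg.dy) == pytest.approx(
            cfg.mean_velocity * cfg.radius, rel=1e-12)

    def test_rest_state_zero_fields(self):
        state = build_lattice(SimulationConfig())
        ff = macroscopic_fields(state)
        assert np.allclose(ff.ux, 0.0)
        assert np.allclose(ff.uy, 0.0)
        assert np.allclose(ff.p, 0.0, atol=1e-12)

    def test_flow_field_h5_round_trip(self, tmp_path, steady_default):
        import h5py

        from gutmix.lbm_flow import save_flow_field_h5

        _, _, ff = steady_default
        p = tmp_path / "field.h5"
        save_flow_field_h5(ff, p)
        with h5py.File(p) as f:
            assert np.array_equal(f["ux"][...], ff.ux)
            assert f.attrs["dy_m"] == ff.dy


class TestPoiseuille:
    def test_profile_within_one_percent(self, steady_default):
        cfg, _, ff = steady_default
        eta = np.arange(cfg.ny + 1) / cfg.ny
        exact = 1.5 * cfg.mean_velocity * (1 - eta**2)
        mid = ff.ux[:, cfg.nx // 2]
        err = np.linalg.norm(mid - exact) / np.linalg.norm(exact)
        assert err < 0.01
        assert mid[0] / cfg.mean_velocity == pytest.approx(1.5, rel=0.01)

    def test_mass_flux_conserved(self, steady_default):
        _, _, ff = steady_default
        flux = ff.axial_flux()
        assert abs(flux[0] - flux[-1]) / flux[0] < 1e-3
        # and uniform along the whole channel
        assert np.ptp(flux) / flux[0] < 1e-3

    def test_error_shrinks_with_refinement(self, steady_default):
        cfg, _, ff = steady_default
        eta = np.arange(cfg.ny + 1) / cfg.ny
        exact = 1.5 * cfg.mean_velocity * (1 - eta**2)
        coarse_err = np.linalg.norm(ff.ux[:, cfg.nx // 2] - exact) \
            / np.linalg.norm(exact)

        fine = SimulationConfig(nx=1000, ny=20)
        state = build_lattice(fine)
        _init_equilibrium(state, np.broadcast_to(
            state._ux_in[:, None], (fine.ny + 1, fine.nx + 1)))
        run_to_steady(state, 0.0, tol=1e-9)
        ff2 = macroscopic_fields(state)
        eta2 = np.arange(fine.ny + 1) / fine.ny
        exact2 = 1.5 * fine.mean_velocity * (1 - eta2**2)
        fine_err = np.linalg.norm(ff2.ux[:, fine.nx // 2] - exact2) \
            / np.linalg.norm(exact2)
        assert fine_err < coarse_err

    def test_creeping_linearity(self, small_sim_config):
        # Stokes flow: doubling the perfusion doubles the whole field
        def steady_ux(scale):
            cfg = SimulationConfig(
                length=0.05, nx=125, ny=5, flow_rate=0.16 * scale)
            state = build_lattice(cfg)
            _init_equilibrium(state, np.broadcast_to(
                state._ux_in[:, None], (cfg.ny + 1, cfg.nx + 1)))
            run_to_steady(state, 0.0, tol=1e-9)
            return macroscopic_fields(state).ux

        u1, u2 = steady_ux(1.0), steady_ux(2.0)
        assert np.allclose(u2, 2.0 * u1, rtol=1e-4,
                           atol=1e-7 * np.abs(u1).max())


class TestMovingWall:
    def test_steady_uniform_drag(self):
        # zero pressure at both ends + uniformly moving wall: the wall
        # drags the whole half-channel, u == u_w everywhere (Couette
        # degenerate because du/dy = 0 at the symmetry line)
        cfg = SimulationConfig(length=0.05, nx=125, ny=5,
                               inlet_mode="pressure")
        state = build_lattice(cfg)
        uw = 1e-3
        for _ in range(6000):
            step_flow(state, uw)
        ff = macroscopic_fields(state)
        mid = ff.ux[:, 40:85]
        assert np.allclose(mid, uw, rtol=0.02)

    def test_oscillating_wall_matches_fd_oracle(self):
        # independent Crank-Nicolson Navier-Stokes (Stokes-layer) solve
        cfg = SimulationConfig(length=0.05, nx=125, ny=5,
                               inlet_mode="pressure",
                               wall_speed_estimate=2e-3)
        state = build_lattice(cfg)
        dt = state.unit_map.dt
        freq, amp = 0.5, 2e-3
        t_end = 4.0 / freq  # four periods
        nsteps = int(round(t_end / dt))
        for n in range(1, nsteps + 1):
            step_flow(state, amp * np.sin(2 * np.pi * freq * n * dt))
        ff = macroscopic_fields(state)
        y = np.arange(cfg.ny + 1) * cfg.dy
        exact = stokes_layer_profile(
            y, cfg.radius, cfg.kinematic_viscosity, freq, amp,
            t_end=nsteps * dt)
        err = np.abs(ff.ux[:, cfg.nx // 2] - exact).max() / amp
        assert err < 0.05

    def test_slow_varying_wall_matches_lubrication(self, short_map):
        # quasi-steady regime: per-column profile is alpha + beta y^2 with
        # the flux pinned by the inlet
        from gutmix.pendular_synth import (
            PendularConfig, generate_strain_rate_map, strain_to_wall_velocity)

        pc = PendularConfig(n_domains=4, amplitude=0.4, frequency=0.02,
                            duration=30.0, seed=11, modulation_depth=0.0)
        srmap = generate_strain_rate_map(pc)
        cfg = SimulationConfig(wall_speed_estimate=8e-3, duration=30.0)
        state = build_lattice(cfg)
        _init_equilibrium(state, np.broadcast_to(
            state._ux_in[:, None], (cfg.ny + 1, cfg.nx + 1)))
        run_to_steady(state, 0.0, tol=1e-8)
        dt = state.unit_map.dt
        u_w = strain_to_wall_velocity(srmap)
        x_grid = np.linspace(0, cfg.length, cfg.nx + 1)
        nsteps = int(round(12.5 / dt))  # quarter period: peak wall speed
        for n in range(1, nsteps + 1):
            t = n * dt
            j = np.searchsorted(srmap.t_axis, t) - 1
            w = (t - srmap.t_axis[j]) / (srmap.t_axis[j + 1] - srmap.t_axis[j])
            uw_x = np.interp(x_grid, srmap.x_axis,
                             (1 - w) * u_w[:, j] + w * u_w[:, j + 1])
            step_flow(state, uw_x)
        ff = macroscopic_fields(state)
        y = np.arange(cfg.ny + 1) * cfg.dy
        q = cfg.mean_velocity * cfg.radius
        # compare at the columns with the largest wall speeds
        cols = np.argsort(np.abs(uw_x))[-10:]
        for col in cols:
            if col < 20 or col > cfg.nx - 20:
                continue  # end regions feel the inlet/outlet conditions
            exact = lubrication_profile(y, cfg.radius, uw_x[col], q)
            err = np.abs(ff.ux[:, col] - exact).max()
            assert err < 0.05 * (abs(uw_x[col]) + cfg.mean_velocity)

    def test_wall_only_flux_uniform_and_zero_mean(self):
        # pendular drive with both ends at equal pressure: the section
        # flux equals the wall-induced flux everywhere and time-averages
        # to ~0 (non-propulsive)
        from gutmix.pendular_synth import (
            PendularConfig, generate_strain_rate_map, strain_to_wall_velocity)

        pc = PendularConfig(n_domains=4, amplitude=0.4, frequency=0.02,
                            duration=60.0, seed=3, modulation_depth=0.0,
                            frequency_jitter=0.0)
        srmap = generate_strain_rate_map(pc)
        cfg = SimulationConfig(length=0.05, nx=125, ny=5,
                               inlet_mode="pressure",
                               wall_speed_estimate=8e-3)
        state = build_lattice(cfg)
        dt = state.unit_map.dt
        u_w = strain_to_wall_velocity(srmap)
        x_grid = np.linspace(0, cfg.length, cfg.nx + 1)
        x_map = np.clip(x_grid, srmap.x_axis[0], srmap.x_axis[-1])
        nsteps = int(round(50.0 / dt))  # one full period
        fluxes = []
        scale = 8e-3 * cfg.radius  # wall-velocity flux scale
        for n in range(1, nsteps + 1):
            t = n * dt
            j = min(np.searchsorted(srmap.t_axis, t) - 1,
                    srmap.t_axis.size - 2)
            w = (t - srmap.t_axis[j]) / (srmap.t_axis[j + 1] - srmap.t_axis[j])
            uw_x = np.interp(x_map, srmap.x_axis,
                             (1 - w) * u_w[:, j] + w * u_w[:, j + 1])
            step_flow(state, uw_x)
            if n % 200 == 0:
                flux = macroscopic_fields(state).axial_flux()
                fluxes.append(flux[10:-10])
        fluxes = np.asarray(fluxes)
        # instantaneous flux uniform along the channel
        assert np.ptp(fluxes, axis=1).max() < 0.05 * scale
        # and averages out over the oscillation
        assert abs(fluxes.mean()) < 0.05 * scale


class TestChannelStokes:
    def test_poiseuille_steady_state_exact(self):
        cfg = SimulationConfig()
        flow = ChannelStokesFlow(cfg, dt=2.5e-3)
        u0 = flow.ux.copy()
        for _ in range(500):
            flow.step(np.zeros(cfg.nx + 1))
        assert np.allclose(flow.ux, u0, atol=1e-14)
        assert np.allclose(flow.uy, 0.0, atol=1e-14)

    def test_womersley_closed_form(self):
        # oscillating wall at alpha ~ 3.5: compare with the complex
        # cosh-profile solution of the flux-constrained Stokes problem
        cfg = SimulationConfig()
        dt, freq, amp = 2.5e-3, 0.5, 3e-3
        flow = ChannelStokesFlow(cfg, dt, flow_rate_scale=0.0)
        amp_lat = amp * dt / cfg.dx
        nsteps = int(round(10 / freq / dt))
        for n in range(1, nsteps + 1):
            flow.step(np.full(cfg.nx + 1,
                              amp_lat * np.sin(2 * np.pi * freq * n * dt)))
        h, nu, w = cfg.radius, cfg.kinematic_viscosity, 2 * np.pi * freq
        k = np.sqrt(1j * w / nu)
        y = np.linspace(0, h, cfg.ny + 1)
        M = np.array([[np.cosh(k * h), 1.0], [np.sinh(k * h) / k, h]])
        A, B = np.linalg.solve(M, [1.0, 0.0])
        uhat = A * np.cosh(k * y) + B
        t_end = nsteps * dt
        exact = np.real(amp * uhat * np.exp(1j * w * t_end) / 1j)
        sim = flow.ux[:, cfg.nx // 2] * cfg.dx / dt
        assert np.abs(sim - exact).max() / amp < 0.01

    def test_flux_pinned_every_step(self, short_map):
        from gutmix.pendular_synth import strain_to_wall_velocity

        cfg = SimulationConfig()
        dt = 2.5e-3
        flow = ChannelStokesFlow(cfg, dt)
        u_w = strain_to_wall_velocity(short_map)
        x_grid = np.linspace(0, cfg.length, cfg.nx + 1)
        w = np.ones(cfg.ny + 1)
        w[0] = w[-1] = 0.5
        target = flow._q_target
        for n in range(1, 400):
            uw_x = np.interp(x_grid, short_map.x_axis, u_w[:, n % 200]) \
                * dt / cfg.dx
            flow.step(uw_x)
            flux = (w[:, None] * flow.ux).sum(axis=0)
            assert np.allclose(flux, target, atol=1e-12)

    def test_agrees_with_lbm_at_slow_oscillation(self):
        # dual-route check: the weakly-compressible lattice and the
        # incompressible solver must agree where both are valid
        from gutmix.pendular_synth import (
            PendularConfig, generate_strain_rate_map, strain_to_wall_velocity)

        pc = PendularConfig(n_domains=4, amplitude=0.4, frequency=0.02,
                            duration=30.0, seed=11, modulation_depth=0.0)
        srmap = generate_strain_rate_map(pc)
        cfg = SimulationConfig(wall_speed_estimate=8e-3)
        state = build_lattice(cfg)
        _init_equilibrium(state, np.broadcast_to(
            state._ux_in[:, None], (cfg.ny + 1, cfg.nx + 1)))
        run_to_steady(state, 0.0, tol=1e-8)
        dt = state.unit_map.dt
        flow = ChannelStokesFlow(cfg, dt)
        u_w = strain_to_wall_velocity(srmap)
        x_grid = np.linspace(0, cfg.length, cfg.nx + 1)
        nsteps = int(round(12.5 / dt))
        for n in range(1, nsteps + 1):
            t = n * dt
            j = np.searchsorted(srmap.t_axis, t) - 1
            wgt = (t - srmap.t_axis[j]) / (srmap.t_axis[j + 1] - srmap.t_axis[j])
            uw_x = np.interp(x_grid, srmap.x_axis,
                             (1 - wgt) * u_w[:, j] + wgt * u_w[:, j + 1])
            step_flow(state, uw_x)
            flow.step(uw_x * dt / cfg.dx)
        lbm_ux = macroscopic_fields(state).ux
        stokes_ux = flow.ux * cfg.dx / dt
        scale = np.abs(stokes_ux).max()
        interior = slice(None), slice(20, -20)
        assert np.abs(lbm_ux[interior] - stokes_ux[interior]).max() < 0.05 * scale
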