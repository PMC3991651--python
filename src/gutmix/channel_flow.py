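"""Exactly incompressible unsteady Stokes flow in the half-lumen channel.

At the study's parameters the flow is deep creeping flow (Re ~ 1e-3) but
not quasi-steady: the Womersley number of the 0.5 Hz pendular drive is
about 3.5, so the wall-driven shear is confined to an oscillatory Stokes
layer ~0.8 mm thick.  Because the lumen is long and thin (half-width
2 mm over 10 cm) and the wall moves only tangentially, the axial momentum
balance reduces, to O((h/L)^2), to a per-column unsteady Stokes problem

    du/dt = -G(x,t)/rho + nu d2u/dy2,   u(h) = u_w(x,t),  du/dy(0) = 0,

with the axial pressure gradient G(x, t) determined at every column and
instant by the incompressibility constraint that the axial volume flux
equal the perfusion flux exactly.  The radial velocity follows from
continuity.  This gives a divergence-free unsteady flow field at any time
step affordable for the coupled tracer run — the weakly-compressible
lattice-Boltzmann flow solver remains the reference for steady and
slowly-oscillating regimes, where the two agree, but its pseudo-sound
speed cannot follow the 0.5 Hz lubrication pressure field without
prohibitively small time steps.

The scheme is Crank-Nicolson in time with a Thomas solve per column; the
flux constraint is enforced by superposition (the constant-forcing
response is precomputed once).  All fields are kept in lattice units so
the tracer lattice consumes them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .lbm_flow import SimulationConfig, UnitMap, inlet_profile

__all__ = ["ChannelStokesFlow"]


@njit(cache=True, fastmath=True)
def _cn_step(u, uw_new, uw_old, r, low, cprime, inv_den, uB, wB, q_target,
             dudx, v):
    """One Crank-Nicolson step for all columns, then radial velocity from
    continuity.

    ``u`` has shape (ny+1, nx+1) with row ny the wall; mutated in place.
    ``low``/``cprime``/``inv_den`` hold the precomputed Thomas
    factorisation of the constant tridiagonal matrix; ``uB`` is the
    unit-forcing response whose flux is ``wB``, used to pin the axial flux
    to ``q_target`` by superposition.
    """
    NY, NX = u.shape
    n = NY - 1  # unknown rows 0..n-1
    d = np.empty(n)
    for x in range(NX):
        # explicit half + Dirichlet data at old and new time
        d[0] = u[0, x] + 2.0 * r * (u[1, x] - u[0, x])
        for j in range(1, n - 1):
            d[j] = u[j, x] + r * (u[j - 1, x] - 2.0 * u[j, x] + u[j + 1, x])
        d[n - 1] = (u[n - 1, x]
                    + r * (u[n - 2, x] - 2.0 * u[n - 1, x] + uw_old[x])
                    + r * uw_new[x])
        # Thomas solve (forward sweep then back substitution)
        d[0] = d[0] * inv_den[0]
        for j in range(1, n):
            d[j] = (d[j] - low[j] * d[j - 1]) * inv_den[j]
        for j in range(n - 2, -1, -1):
            d[j] = d[j] - cprime[j] * d[j + 1]
        # flux constraint via the unit-forcing response
        flux_a = 0.5 * d[0] + 0.5 * uw_new[x]
        for j in range(1, n):
            flux_a += d[j]
        gamma = (q_target - flux_a) / wB
        for j in range(n):
            u[j, x] = d[j] + gamma * uB[j]
        u[n, x] = uw_new[x]

    # radial velocity from continuity: v(y) = -int_0^y du/dx dy'
    for y in range(NY):
        for x in range(1, NX - 1):
            dudx[y, x] = 0.5 * (u[y, x + 1] - u[y, x - 1])
        dudx[y, 0] = u[y, 1] - u[y, 0]
        dudx[y, NX - 1] = u[y, NX - 1] - u[y, NX - 2]
    for x in range(NX):
        v[0, x] = 0.0
        for y in range(1, NY):
            v[y, x] = v[y - 1, x] - 0.5 * (dudx[y - 1, x] + dudx[y, x])


class ChannelStokesFlow:
    """Incompressible pendular-driven channel flow on the tracer grid.

    Exposes ``ux``/``uy`` (lattice units) and ``unit_map`` with the same
    conventions as :class:`gutmix.lbm_flow.LatticeState`, so
    :func:`gutmix.tracer_lbm.step_tracer` and
    :func:`gutmix.tracer_lbm.outflow_concentration` accept either driver.
    """

    def __init__(self, config: SimulationConfig, dt: float,
                 flow_rate_scale: float = 1.0):
        self.config = config
        self.unit_map = UnitMap(dx=config.dx, dt=dt, density=config.density)
        self.time = 0.0
        ny, nx = config.ny, config.nx
        profile = np.asarray(
            self.unit_map.velocity_to_lattice(inlet_profile(config))
        ) * flow_rate_scale
        self.ux = np.ascontiguousarray(
            np.broadcast_to(profile[:, None], (ny + 1, nx + 1)).copy()
        )
        self.uy = np.zeros((ny + 1, nx + 1))
        self._dudx = np.zeros((ny + 1, nx + 1))
        w = np.ones(ny + 1)
        w[0] = w[-1] = 0.5
        self._q_target = float((w * profile).sum())
        self._uw_old = np.zeros(nx + 1)

        # Crank-Nicolson tridiagonal prefactorisation (constant matrix)
        nu_lat = config.kinematic_viscosity * dt / config.dx**2
        self._r = 0.5 * nu_lat
        n = ny
        diag = np.full(n, 1.0 + 2.0 * self._r)
        lower = np.full(n, -self._r)
        upper = np.full(n, -self._r)
        upper[0] = -2.0 * self._r
        # Thomas: den_j = diag_j - low_j * upper_{j-1} / den_{j-1}
        den = np.empty(n)
        den[0] = diag[0]
        for j in range(1, n):
            den[j] = diag[j] - lower[j] * upper[j - 1] / den[j - 1]
        self._low = lower
        self._inv_den = 1.0 / den
        self._cprime = upper * self._inv_den

        # unit-forcing response uB: A uB = 1 (wall value 0)
        dB = np.ones(n)
        dB[0] *= self._inv_den[0]
        for j in range(1, n):
            dB[j] = (dB[j] - lower[j] * dB[j - 1]) * self._inv_den[j]
        for j in range(n - 2, -1, -1):
            dB[j] = dB[j] - upper[j] * self._inv_den[j] * dB[j + 1]
        self._uB = dB
        self._wB = float(0.5 * dB[0] + dB[1:].sum())

    @property
    def f(self):  # grid-shape shim for shape checks
        return self.ux[None]

    def step(self, wall_velocity_lat: np.ndarray) -> None:
        """Advance one time step with the new wall velocity (lattice units,
        one value per column)."""
        uw_new = np.asarray(wall_velocity_lat, dtype=float)
        _cn_step(self.ux, uw_new, self._uw_old, self._r, self._low,
                 self._cprime, self._inv_den, self._uB, self._wB,
                 self._q_target, self._dudx, self.uy)
        self._uw_old = uw_new.copy()
        self.time += self.unit_map.dt

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.ux)):
            raise FloatingPointError(
                f"channel flow diverged at t = {self.time:.4f} s"
            )
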