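"""Independent reference computations used by the test suite.

Everything here is deliberately implemented without touching the package's
solvers: closed forms, brute-force quadrature, and small finite-difference
marches, so each serves as an external check on the corresponding gutmix
code path.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def erlang_step_response(n_tanks: int, tau: float, t: float) -> float:
    """Step response of a tanks-in-series cascade by brute-force quadrature
    of the Erlang residence-time density (independent of the gamma-function
    evaluation in the package)."""
    from math import factorial

    rate = n_tanks / tau

    def pdf(s: float) -> float:
        return rate * (rate * s) ** (n_tanks - 1) * np.exp(-rate * s) \
            / factorial(n_tanks - 1)

    val, _ = quad(pdf, 0.0, t, limit=200)
    return val


def boxcar_minute_average(t: np.ndarray, f: np.ndarray, mark: float,
                          window: float = 60.0, n_sub: int = 20000) -> float:
    """Collection-tube average over (mark-window, mark] by dense Riemann
    sum of the linear interpolant."""
    s = np.linspace(mark - window, mark, n_sub)
    vals = np.interp(s, t, f, left=0.0, right=f[-1])
    return float(vals.mean())


def laminar_planar_rtd(t_s: np.ndarray, length: float, mean_velocity: float
                       ) -> np.ndarray:
    """Pure-advection step response of plane Poiseuille flow.

    Streamline y has speed u = 1.5 U (1 - (y/h)^2); the flux-weighted
    fraction with residence time below t has the closed form
    F = (3 eta - eta^3) / 2 with eta^2 = 1 - t0/t, t0 = L / (1.5 U).
    Molecular diffusion is neglected, so this bounds the early-to-mid rise
    of the simulated baseline curve.
    """
    t = np.asarray(t_s, dtype=float)
    t0 = length / (1.5 * mean_velocity)
    eta = np.sqrt(np.clip(1.0 - t0 / np.maximum(t, 1e-12), 0.0, 1.0))
    return np.where(t > t0, 0.5 * (3.0 * eta - eta**3), 0.0)


def stokes_layer_profile(
    y: np.ndarray,
    half_width: float,
    nu: float,
    freq_hz: float,
    wall_amp: float,
    t_end: float,
    dt: float = 1e-3,
    n_nodes: int = 201,
    constrain_flux: bool = False,
) -> np.ndarray:
    """Finite-difference (Crank-Nicolson) solve of the oscillating-wall
    Stokes layer, evaluated at time ``t_end``.

    Solves du/dt = -G(t)/rho + nu u_yy on [0, h] with u(h) = wall_amp *
    sin(2 pi f t) and du/dy(0) = 0.  With ``constrain_flux`` the axial
    pressure gradient G is chosen each step so the net flux vanishes;
    without it G = 0, the reduced Navier-Stokes problem for a uniformly
    oscillating wall between equal-pressure ends.  Implemented with dense
    nodes and plain numpy so it is independent of the package's solvers.
    """
    h = half_width
    yy = np.linspace(0.0, h, n_nodes)
    dy = yy[1] - yy[0]
    u = np.zeros(n_nodes)
    r = 0.5 * nu * dt / dy**2
    n = n_nodes - 1  # unknowns 0..n-1, Dirichlet at n

    main = np.full(n, 1.0 + 2.0 * r)
    lower = np.full(n, -r)
    upper = np.full(n, -r)
    upper[0] = -2.0 * r

    import scipy.linalg as sla

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = main
    ab[2, :-1] = lower[1:]

    w = np.ones(n_nodes)
    w[0] = w[-1] = 0.5
    omega = 2 * np.pi * freq_hz

    nsteps = int(round(t_end / dt))
    for k in range(nsteps):
        t_old = k * dt
        t_new = (k + 1) * dt
        uw_old = wall_amp * np.sin(omega * t_old)
        uw_new = wall_amp * np.sin(omega * t_new)
        d = np.empty(n)
        d[0] = u[0] + 2 * r * (u[1] - u[0])
        d[1:n - 1] = u[1:n - 1] + r * (u[0:n - 2] - 2 * u[1:n - 1] + u[2:n])
        d[n - 1] = (u[n - 1] + r * (u[n - 2] - 2 * u[n - 1] + uw_old)
                    + r * uw_new)
        uA = sla.solve_banded((1, 1), ab, d)
        if constrain_flux:
            uB = sla.solve_banded((1, 1), ab, np.ones(n))
            flux_a = (w[:n] * uA).sum() * dy + 0.5 * uw_new * dy
            flux_b = (w[:n] * uB).sum() * dy
            gamma = (0.0 - flux_a) / flux_b
            u[:n] = uA + gamma * uB
        else:
            u[:n] = uA
        u[n] = uw_new
    return np.interp(y, yy, u)


def lubrication_profile(y: np.ndarray, half_width: float, wall_velocity: float,
                        flux: float) -> np.ndarray:
    """Quasi-steady creeping-flow profile in a thin channel section whose
    wall moves tangentially at ``wall_velocity`` while the section carries
    total flux ``flux`` (per unit depth): u = alpha + beta y^2 with
    u(h) = u_w and the flux constraint."""
    h = half_width
    # alpha + beta h^2 = u_w ; alpha h + beta h^3 / 3 = q
    A = np.array([[1.0, h**2], [h, h**3 / 3.0]])
    alpha, beta = np.linalg.solve(A, [wall_velocity, flux])
    return alpha + beta * np.asarray(y) ** 2
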