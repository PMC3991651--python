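"""Incompressible lattice-Boltzmann flow in a 2D half-lumen channel.

The duodenal lumen is modelled exactly as a straight planar channel of
length 10 cm whose centreline is an axis of symmetry: the computational
domain is the half-channel of width 2 mm (half the 4 mm lumen), with the
wall a geometrically fixed line that moves only tangentially, driven by
the longitudinal strain-rate map of pendular activity.  The inlet carries
a parabolic (Poiseuille) velocity profile whose mean equals the perfusion
velocity U = Q / (pi R^2); the outlet holds zero pressure.  At the
defaults (Q = 0.16 mL/min, 4 mm lumen, water-like viscosity) U is about
2.1e-4 m/s and the Reynolds number about 8e-4 — deep creeping flow.

The solver is a D2Q9 two-relaxation-time (TRT) scheme with the He-Luo
incompressible equilibrium and Zou-He (non-equilibrium bounce-back)
velocity/pressure boundaries.  This is a planar, not axisymmetric,
description: the 3D flow rate enters only through the mean axial velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _lb_kernels as _k

__all__ = [
    "SimulationConfig",
    "UnitMap",
    "LatticeState",
    "FlowField",
    "build_lattice",
    "inlet_profile",
    "step_flow",
    "macroscopic_fields",
    "run_to_steady",
]

CS2 = 1.0 / 3.0  # lattice sound speed squared


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and numerical parameters of the half-lumen simulation.

    All defaults are the study constants: 10 cm segment, 4 mm lumen,
    0.16 mL/min perfusion, 1 mPa.s viscosity, methylene-blue diffusivity
    5e-10 m^2/s.  ``nx`` axial cells and ``ny`` radial cells span the
    length and the half-width; the lattice must be square (length/nx ==
    radius/ny).  ``dt`` may be left None to let :func:`build_lattice`
    choose it from the stability/Mach window given the expected peak wall
    speed.
    """

    length: float = 0.1            # m
    diameter: float = 4e-3         # m
    flow_rate: float = 0.16        # mL/min
    viscosity: float = 1e-3        # Pa s
    density: float = 1e3           # kg/m^3
    diffusivity: float = 5e-10     # m^2/s
    nx: int = 500
    ny: int = 10
    dt: float | None = None        # s; None -> auto from stability window
    duration: float = 900.0        # s
    lambda_flow: float = 3.0 / 16.0   # TRT magic product, flow
    ad_scheme: str = "bgk"            # tracer collision: "bgk" or "magic"
    lambda_ad: float = 1.0 / 4.0      # magic product when ad_scheme="magic"
    inlet_ramp_s: float = 30.0        # dye step rise time at the inlet (s)
    wall_speed_estimate: float = 0.0  # m/s, peak |u_w| used for dt choice
    max_wall_velocity_lat: float = 0.1  # lattice ceiling on wall speed
    tau_plus_target: float = 1.1   # preferred flow relaxation time
    inlet_mode: str = "velocity"   # "velocity" (Poiseuille) or "pressure"
    tracer_tolerance: float = 0.2  # allowed max-principle front overshoot
    limit_tracer_bounds: bool = True  # conservative [0,1] bound limiter

    def __post_init__(self) -> None:
        if min(self.length, self.diameter, self.flow_rate, self.viscosity,
               self.density, self.diffusivity) <= 0:
            raise ValueError("physical constants must be positive")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must have at least 2 cells per direction")
        if abs(self.dx - self.dy) > 1e-12 * self.dx:
            raise ValueError(
                f"lattice must be square: length/nx = {self.dx:g} m but "
                f"radius/ny = {self.dy:g} m (use nx = ny * length / radius)"
            )
        if self.inlet_mode not in ("velocity", "pressure"):
            raise ValueError("inlet_mode must be 'velocity' or 'pressure'")
        if self.ad_scheme not in ("bgk", "magic"):
            raise ValueError("ad_scheme must be 'bgk' or 'magic'")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def dx(self) -> float:
        return self.length / self.nx

    @property
    def dy(self) -> float:
        return self.radius / self.ny

    @property
    def mean_velocity(self) -> float:
        """Mean axial velocity U = Q / (pi R^2) in m/s (~2.12e-4 default)."""
        q_m3s = self.flow_rate * 1e-6 / 60.0
        return q_m3s / (np.pi * self.radius**2)

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density

    def reynolds_number(self) -> float:
        return self.density * self.mean_velocity * self.diameter / self.viscosity

    def admissible_dt_range(self) -> tuple[float, float]:
        """dt window keeping the flow relaxation time in (0.5, 2) and the
        wall/inlet velocities below the lattice ceiling."""
        nu = self.kinematic_viscosity
        dt_tau_max = 0.5 * self.dx**2 / nu  # tau_plus = 2
        u_peak = 1.5 * self.mean_velocity + self.wall_speed_estimate
        dt_mach = self.max_wall_velocity_lat * self.dx / u_peak
        return 0.0, min(dt_tau_max, dt_mach)

    def resolve_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        nu = self.kinematic_viscosity
        dt_tau = (self.tau_plus_target - 0.5) / 3.0 * self.dx**2 / nu
        _, dt_max = self.admissible_dt_range()
        return min(dt_tau, dt_max)


@dataclass(frozen=True)
class UnitMap:
    """Lattice <-> physical unit conversion (dx in m, dt in s, density scale)."""

    dx: float
    dt: float
    density: float

    def velocity_to_lattice(self, u: np.ndarray | float):
        return np.asarray(u) * self.dt / self.dx

    def velocity_to_physical(self, u: np.ndarray | float):
        return np.asarray(u) * self.dx / self.dt

    def pressure_to_physical(self, rho_lat: np.ndarray | float, rho_ref: float = 1.0):
        return (np.asarray(rho_lat) - rho_ref) * CS2 * self.density \
            * (self.dx / self.dt) ** 2

    def diffusivity_to_lattice(self, d: float) -> float:
        return d * self.dt / self.dx**2


@dataclass
class LatticeState:
    """D2Q9 populations plus unit map and clock for the half-lumen flow."""

    f: np.ndarray          # (9, ny+1, nx+1)
    config: SimulationConfig
    unit_map: UnitMap
    time: float = 0.0
    tau_plus: float = 0.0
    # scratch and cached macroscopic fields (lattice units)
    _fpost: np.ndarray = field(default=None, repr=False)
    ux: np.ndarray = field(default=None, repr=False)
    uy: np.ndarray = field(default=None, repr=False)
    rho: np.ndarray = field(default=None, repr=False)
    _ux_in: np.ndarray = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.f.shape[1], self.f.shape[2]

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.f)):
            bad = np.argwhere(~np.isfinite(self.f))[0]
            raise FloatingPointError(
                f"flow diverged at t = {self.time:.4f} s "
                f"(direction {bad[0]}, row {bad[1]}, column {bad[2]})"
            )
        if self.f.min() < -1e-6:
            bad = np.unravel_index(np.argmin(self.f), self.f.shape)
            raise FloatingPointError(
                f"negative population at t = {self.time:.4f} s "
                f"(direction {bad[0]}, row {bad[1]}, column {bad[2]})"
            )


def inlet_profile(config: SimulationConfig, ny: int | None = None) -> np.ndarray:
    """Parabolic inlet profile u_x(y) in m/s on rows 0..ny (0 = centreline).

    Zero at the wall, maximum 1.5 U at the symmetry line, discretely
    renormalised so the trapezoidal integral equals U * half-width exactly
    (the renormalisation is an O(ny^-2) correction, ~0.25 % at ny = 10).
    """
    ny = config.ny if ny is None else ny
    eta = np.arange(ny + 1) / ny  # 0 centreline .. 1 wall
    u = 1.5 * config.mean_velocity * (1.0 - eta**2)
    target = config.mean_velocity * config.radius
    u *= target / np.trapezoid(u, dx=config.radius / ny)
    return u


def build_lattice(config: SimulationConfig) -> LatticeState:
    """Initialise a lattice at rest with uniform pressure.

    Rejects parameter combinations whose TRT relaxation time falls outside
    the stable window (0.5, 2) or whose velocities exceed the lattice
    ceiling, reporting the admissible dt range.
    """
    dt = config.resolve_dt()
    nu_lat = config.kinematic_viscosity * dt / config.dx**2
    tau_plus = 0.5 + 3.0 * nu_lat
    _, dt_max = config.admissible_dt_range()
    if not (0.5 < tau_plus < 2.0) or dt > dt_max * (1 + 1e-9):
        raise ValueError(
            f"dt = {dt:g} s outside the stable window: admissible dt in "
            f"(0, {dt_max:g}) s for this grid and viscosity "
            f"(relaxation time tau = {tau_plus:g} must lie in (0.5, 2))"
        )
    u_lat = 1.5 * config.mean_velocity * dt / config.dx
    if u_lat / np.sqrt(CS2) >= 0.1:
        raise ValueError(
            f"lattice Mach number {u_lat / np.sqrt(CS2):g} >= 0.1; reduce dt "
            f"(admissible dt in (0, {dt_max:g}) s)"
        )

    unit_map = UnitMap(dx=config.dx, dt=dt, density=config.density)
    ny, nx = config.ny, config.nx
    f = np.empty((9, ny + 1, nx + 1))
    w = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9,
                  1 / 36, 1 / 36, 1 / 36, 1 / 36])
    f[:] = w[:, None, None]  # equilibrium at rest, rho = 1
    state = LatticeState(f=f, config=config, unit_map=unit_map,
                         tau_plus=tau_plus)
    state._fpost = np.empty_like(f)
    state.ux = np.zeros((ny + 1, nx + 1))
    state.uy = np.zeros((ny + 1, nx + 1))
    state.rho = np.ones((ny + 1, nx + 1))
    state._ux_in = unit_map.velocity_to_lattice(inlet_profile(config))
    return state


def _omegas(tau_plus: float, magic: float) -> tuple[float, float]:
    tau_minus = 0.5 + magic / (tau_plus - 0.5)
    return 1.0 / tau_plus, 1.0 / tau_minus


def step_flow(
    state: LatticeState,
    wall_velocity: np.ndarray | float = 0.0,
    rho_in: float = 1.0,
    rho_out: float = 1.0,
) -> LatticeState:
    """Advance the flow one lattice step under the given wall velocity.

    ``wall_velocity`` is the tangential wall speed in m/s, a scalar or an
    array over the nx+1 columns (sampled from the strain-rate map at the
    state's current time).  Mutates and returns ``state``.
    """
    cfg = state.config
    uw = np.broadcast_to(
        state.unit_map.velocity_to_lattice(wall_velocity), (cfg.nx + 1,)
    ).astype(float)
    omega_p, omega_m = _omegas(state.tau_plus, cfg.lambda_flow)
    _k.flow_step(
        state.f, state._fpost, state.ux, state.uy, state.rho,
        omega_p, omega_m, state._ux_in, uw, rho_in, rho_out,
        cfg.inlet_mode == "pressure",
    )
    state.time += state.unit_map.dt
    return state


@dataclass
class FlowField:
    """Macroscopic velocity (m/s) and pressure deviation (Pa) on the grid.

    Row 0 is the centreline, the last row the wall; column 0 the inlet.
    """

    ux: np.ndarray
    uy: np.ndarray
    p: np.ndarray
    dy: float
    time: float = 0.0

    def axial_flux(self) -> np.ndarray:
        """Net axial volume flux per unit depth (m^2/s) at every column,
        by trapezoidal quadrature over the half-width."""
        return np.trapezoid(self.ux, dx=self.dy, axis=0)


def macroscopic_fields(state: LatticeState) -> FlowField:
    """Velocity and pressure from the current populations, physical units."""
    f = state.f
    rho = f.sum(axis=0)
    ux = f[1] - f[3] + f[5] - f[6] - f[7] + f[8]
    uy = f[2] - f[4] + f[5] + f[6] - f[7] - f[8]
    um = state.unit_map
    return FlowField(
        ux=np.asarray(um.velocity_to_physical(ux)),
        uy=np.asarray(um.velocity_to_physical(uy)),
        p=np.asarray(um.pressure_to_physical(rho)),
        dy=state.config.dy,
        time=state.time,
    )


def save_flow_field_h5(field: FlowField, path) -> None:
    """Write a velocity/pressure snapshot to HDF5 (datasets ux, uy, p in
    SI units; attrs carry the grid spacing and time)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("ux", data=field.ux)
        f.create_dataset("uy", data=field.uy)
        f.create_dataset("p", data=field.p)
        f.attrs["dy_m"] = field.dy
        f.attrs["time_s"] = field.time
        f.attrs["units"] = "m/s, m/s, Pa"


def run_to_steady(
    state: LatticeState,
    wall_velocity: np.ndarray | float = 0.0,
    tol: float = 1e-6,
    check_every: int = 200,
    max_steps: int = 40000,
) -> int:
    """Iterate until the relative velocity change over a check interval
    drops below ``tol``.  Returns the number of steps taken."""
    prev = state.ux.copy()
    for n in range(1, max_steps + 1):
        step_flow(state, wall_velocity)
        if n % check_every == 0:
            scale = max(np.abs(state.ux).max(), 1e-30)
            if np.abs(state.ux - prev).max() < tol * scale:
                state.check_finite()
                return n
            prev = state.ux.copy()
    state.check_finite()
    return max_steps
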