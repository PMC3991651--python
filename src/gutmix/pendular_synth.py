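"""Synthetic pendular-activity motility: strain-rate maps and marker images.

Pendular activity is non-propagating longitudinal contraction: a handful of
contiguous spatial domains along the gut alternately lengthen and shorten
with no net propulsion.  Ex-vivo rat duodenum shows 3-5 such domains with
longitudinal strain-rate amplitudes of 0.3-0.5 1/s.  With both ends
cannulated the total segment length is fixed, so the spatial integral of
the strain rate vanishes at every instant; the wall velocity obtained by
integrating the strain rate from the oral end is therefore pinned to zero
at both ends.

The oscillation frequency is NOT constrained by the available motility
statistics; the default of 0.5 Hz matches rat duodenal slow-wave-paced
contraction rates and is an explicit, configurable modelling choice.

This module also renders speckle-textured tube image sequences whose
texture is advected by a given strain-rate map, providing a ground-truthed
fixture for the spatiotemporal mapping stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PendularConfig",
    "StrainRateMap",
    "generate_strain_rate_map",
    "strain_to_wall_velocity",
    "generate_marker_images",
    "save_strain_rate_map_h5",
    "load_strain_rate_map_h5",
    "save_strain_rate_map_csv",
    "load_strain_rate_map_csv",
]


@dataclass(frozen=True)
class PendularConfig:
    """Parameters of a synthetic pendular-activity sequence.

    Attributes
    ----------
    n_domains
        Number of contiguous contractile domains along the segment
        (physiological range 3-5).
    amplitude
        Peak longitudinal strain rate in 1/s (physiological 0.3-0.5).
    frequency
        Oscillation frequency in Hz.  Not constrained by the motility data;
        0.5 Hz default, see module docstring.  Each domain oscillates at
        its own frequency drawn within ``frequency_jitter`` of this value,
        so domains slowly drift out of phase as observed maps do.
    frequency_jitter
        Fractional spread of the per-domain frequencies.
    modulation_time, modulation_depth
        Correlation time (s) and fractional depth of the slow random
        amplitude modulation of each domain.  Recorded pendular activity
        waxes and wanes over tens of seconds rather than holding a pure
        tone; depth 0 gives stationary envelopes.
    length
        Segment length in metres (0.1 m duodenal default).
    duration
        Sequence duration in seconds (900 s = 15 min default).
    dx, dt_map
        Spatial and temporal grid steps of the map (m, s).
    seed
        RNG seed controlling domain-boundary jitter and phase jitter.
    boundary_jitter
        Fractional jitter of the equal-partition domain boundaries.
    allow_out_of_range
        Permit n_domains or amplitude outside the physiological bands.
    """

    n_domains: int = 4
    amplitude: float = 0.4
    frequency: float = 0.5
    length: float = 0.1
    duration: float = 900.0
    dx: float = 1e-3
    dt_map: float = 0.2
    seed: int = 0
    boundary_jitter: float = 0.15
    frequency_jitter: float = 0.05
    modulation_time: float = 60.0
    modulation_depth: float = 0.35
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt_map <= 0:
            raise ValueError("grid steps dx and dt_map must be positive")
        if self.length <= 0 or self.duration <= 0:
            raise ValueError("length and duration must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.n_domains < 1:
            raise ValueError("need at least one contractile domain")
        if not self.allow_out_of_range:
            if not (3 <= self.n_domains <= 5):
                raise ValueError(
                    "n_domains outside the physiological range 3-5 "
                    "(set allow_out_of_range=True to override)"
                )
            if self.amplitude != 0 and not (0.3 <= self.amplitude <= 0.5):
                raise ValueError(
                    "amplitude outside the physiological range 0.3-0.5 1/s "
                    "(set allow_out_of_range=True to override)"
                )


@dataclass
class StrainRateMap:
    """Longitudinal strain rate d(eps)/dt on an (x, t) grid.

    ``values[i, j]`` is the strain rate in 1/s at position ``x_axis[i]``
    (metres from the oral end) and time ``t_axis[j]`` (seconds).  Sign
    convention: positive = local lengthening (relaxation).  Invariants: the
    spatial integral over the segment vanishes at every time slice (fixed
    total length, both ends cannulated) and ``|values|`` never exceeds the
    configured amplitude ceiling.
    """

    values: np.ndarray
    x_axis: np.ndarray
    t_axis: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        if self.values.shape != (self.x_axis.size, self.t_axis.size):
            raise ValueError("values must have shape (len(x_axis), len(t_axis))")

    @property
    def length(self) -> float:
        return float(self.x_axis[-1] - self.x_axis[0])

    def spatial_integral(self) -> np.ndarray:
        """Integral of the strain rate over x at each time — the net rate of
        length change, zero for a segment fixed at both ends."""
        return np.trapezoid(self.values, self.x_axis, axis=0)

    def check_invariants(self, amplitude_ceiling: float | None = None,
                         tol: float = 1e-9) -> None:
        net = self.spatial_integral()
        scale = max(np.abs(self.values).max() * self.length, 1.0)
        if np.abs(net).max() > tol * scale + 1e-15:
            raise ValueError("strain-rate map violates zero net-length-change")
        if amplitude_ceiling is not None:
            if np.abs(self.values).max() > amplitude_ceiling + 1e-12:
                raise ValueError("strain rate exceeds the amplitude ceiling")


def _domain_profiles(x: np.ndarray, edges: np.ndarray, taper_frac: float = 0.25
                     ) -> np.ndarray:
    """Smooth bump profile per domain: 1 in the core, cosine-tapered to 0 at
    the domain edges.  Returns shape (n_domains, len(x))."""
    n = len(edges) - 1
    profiles = np.zeros((n, x.size))
    for k in range(n):
        a, b = edges[k], edges[k + 1]
        width = b - a
        taper = taper_frac * width
        core = np.ones_like(x)
        core[(x < a) | (x > b)] = 0.0
        rise = (x - a) / taper
        fall = (b - x) / taper
        shape = np.minimum(np.clip(rise, 0, 1), np.clip(fall, 0, 1))
        profiles[k] = core * 0.5 * (1 - np.cos(np.pi * shape))
    return profiles


def _slow_envelope(rng: np.random.Generator, t: np.ndarray,
                   corr_time: float, depth: float) -> np.ndarray:
    """Smooth positive random envelope with unit mean level: 1 + depth * s(t)
    where s is filtered standard noise with the given correlation time."""
    if depth == 0:
        return np.ones_like(t)
    from scipy.ndimage import gaussian_filter1d

    dt = t[1] - t[0] if t.size > 1 else 1.0
    raw = rng.normal(size=t.size)
    s = gaussian_filter1d(raw, sigma=max(corr_time / dt, 1.0), mode="reflect")
    sd = s.std()
    if sd > 0:
        s = s / sd
    env = 1.0 + depth * s
    return np.clip(env, 0.1, None)


def generate_strain_rate_map(config: PendularConfig) -> StrainRateMap:
    """Build a pendular-activity L map from a :class:`PendularConfig`.

    The segment is partitioned into ``n_domains`` contiguous domains with
    seeded jitter of the equal-partition boundaries.  Adjacent domains
    oscillate in antiphase (when one lengthens its neighbour shortens);
    each domain has its own phase, a slightly detuned frequency, and a
    slow random amplitude envelope, reflecting the waxing-and-waning,
    drifting character of recorded pendular activity rather than a pure
    standing tone.  After construction the instantaneous spatial mean is
    subtracted to enforce zero net length change exactly, and the map is
    rescaled so the prescribed amplitude is the pointwise maximum — both
    invariants hold by construction.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    nx = int(round(config.length / config.dx)) + 1
    nt = int(round(config.duration / config.dt_map)) + 1
    x = np.linspace(0.0, config.length, nx)
    t = np.linspace(0.0, config.duration, nt)

    if config.amplitude == 0:
        return StrainRateMap(np.zeros((nx, nt)), x, t)

    edges = np.linspace(0.0, config.length, config.n_domains + 1)
    interior = edges[1:-1]
    if interior.size:
        jitter = rng.uniform(-1, 1, interior.size)
        interior = interior + jitter * config.boundary_jitter * (
            config.length / config.n_domains
        )
        edges = np.concatenate(([0.0], np.sort(interior), [config.length]))
    profiles = _domain_profiles(x, edges)

    signs = (-1.0) ** np.arange(config.n_domains)
    phases = rng.uniform(0.0, 2 * np.pi, config.n_domains)
    freqs = config.frequency * (
        1.0 + config.frequency_jitter * rng.uniform(-1, 1, config.n_domains)
    )
    osc = np.empty((config.n_domains, nt))
    for k in range(config.n_domains):
        env = _slow_envelope(rng, t, config.modulation_time,
                             config.modulation_depth)
        osc[k] = env * np.sin(2 * np.pi * freqs[k] * t + phases[k])
    values = np.einsum("kx,kt->xt", profiles * signs[:, None], osc)

    # enforce zero net length change, then pin the peak to the amplitude
    values -= np.trapezoid(values, x, axis=0) / config.length
    peak = np.abs(values).max()
    if peak > 0:
        values *= config.amplitude / peak
    return StrainRateMap(values, x, t)


def strain_to_wall_velocity(srmap: StrainRateMap, tol: float = 1e-6) -> np.ndarray:
    """Longitudinal wall velocity u_w(x, t) implied by a strain-rate map.

    The strain rate is the spatial gradient of the wall velocity, so
    ``u_w(x, t)`` is the cumulative trapezoidal integral of d(eps)/dt from
    the oral end.  The zero-net-length invariant guarantees
    ``u_w(0) = u_w(L) = 0``; maps violating it beyond ``tol`` (relative to
    amplitude x length) are rejected.  Returns an array shaped like
    ``srmap.values`` in m/s.
    """
    scale = max(np.abs(srmap.values).max() * srmap.length, 1e-30)
    net = srmap.spatial_integral()
    if np.abs(net).max() > tol * scale:
        raise ValueError(
            "map violates the zero net-length-change invariant; "
            "wall velocity would not vanish at the aboral end"
        )
    dx = np.diff(srmap.x_axis)[:, None]
    seg = 0.5 * (srmap.values[1:] + srmap.values[:-1]) * dx
    u_w = np.concatenate([np.zeros((1, srmap.t_axis.size)), np.cumsum(seg, axis=0)])
    return u_w


def generate_marker_images(
    srmap: StrainRateMap,
    pixel_size: float = 0.13e-3,
    fps: float = 5.0,
    seed: int = 0,
    height_px: int = 48,
    diameter_profile: np.ndarray | None = None,
    texture_scale_px: float = 4.0,
    background: float = 0.05,
) -> np.ndarray:
    """Render a speckle-textured tube sequence advected by a strain-rate map.

    Frames show a horizontal tube silhouette carrying a fixed random
    speckle texture (standing in for the vascular arcades real recordings
    track).  The texture is displaced along x by the time-integrated wall
    velocity field of the map, so windowed cross-correlation of successive
    frames recovers the map — a round-trip fixture for the mapping stage.

    Parameters default to the recording geometry of the motility setup:
    0.13 mm/pixel at 5 frames/s.  ``diameter_profile`` (metres, per pixel
    column or broadcastable) imposes a tube width for diameter-map tests;
    the default fills 60 % of the frame height.  Returns a float array
    (n_frames, height_px, width_px) in [0, 1].
    """
    if pixel_size <= 0 or fps <= 0:
        raise ValueError("pixel_size and fps must be positive")
    rng = np.random.default_rng(seed)
    width_px = int(round(srmap.length / pixel_size)) + 1
    x_px = np.arange(width_px) * pixel_size

    n_frames = int(np.floor(srmap.t_axis[-1] * fps)) + 1
    frame_times = np.arange(n_frames) / fps

    u_w = strain_to_wall_velocity(srmap)  # (nx_map, nt_map)

    # cumulative displacement of tissue initially at x, integrated at map dt
    dt_map = np.diff(srmap.t_axis)
    disp_map = np.concatenate(
        [np.zeros((srmap.x_axis.size, 1)),
         np.cumsum(0.5 * (u_w[:, 1:] + u_w[:, :-1]) * dt_map[None, :], axis=1)],
        axis=1,
    )

    # smooth speckle texture, fixed for the whole sequence
    raw = rng.normal(size=width_px * 3)
    kernel_w = max(int(texture_scale_px * 2), 3)
    kernel = np.exp(-0.5 * (np.arange(-kernel_w, kernel_w + 1) / texture_scale_px) ** 2)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")[:width_px]
    smooth = (smooth - smooth.min()) / max(np.ptp(smooth), 1e-12)
    texture = 0.25 + 0.7 * smooth

    if diameter_profile is None:
        diameter_profile = np.full(width_px, 0.6 * height_px * pixel_size)
    diameter_px = np.broadcast_to(
        np.asarray(diameter_profile) / pixel_size, (width_px,)
    )

    y = np.arange(height_px)[:, None]
    centre = (height_px - 1) / 2.0
    frames = np.empty((n_frames, height_px, width_px))
    for i, tf in enumerate(frame_times):
        # displacement of the tissue at each map node at this frame time
        d = np.array([
            np.interp(tf, srmap.t_axis, disp_map[k])
            for k in range(srmap.x_axis.size)
        ])
        # Eulerian warp: intensity at x comes from material near x - d(x)
        d_px = np.interp(x_px, srmap.x_axis, d) / pixel_size
        src = np.arange(width_px) - d_px
        row = np.interp(src, np.arange(width_px), texture)
        # antialiased silhouette: one-pixel soft edge so a band of
        # diameter/pixel rows (fractional included) reads back exactly
        coverage = np.clip(
            diameter_px[None, :] / 2.0 - np.abs(y - centre) + 0.5, 0.0, 1.0
        )
        frames[i] = background + coverage * (row[None, :] - background)
    return frames


# ---------------------------------------------------------------------------
# persistence

def save_strain_rate_map_h5(srmap: StrainRateMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=srmap.values)
        f.create_dataset("x_axis", data=srmap.x_axis)
        f.create_dataset("t_axis", data=srmap.t_axis)
        f.attrs["units_values"] = "1/s"
        f.attrs["units_x"] = "m"
        f.attrs["units_t"] = "s"


def load_strain_rate_map_h5(path) -> StrainRateMap:
    import h5py

    with h5py.File(path, "r") as f:
        return StrainRateMap(f["values"][...], f["x_axis"][...], f["t_axis"][...])


def save_strain_rate_map_csv(srmap: StrainRateMap, path) -> None:
    """Long-format CSV (x, t, value) — interoperable but bulky; HDF5 preferred."""
    import pandas as pd

    xg, tg = np.meshgrid(srmap.x_axis, srmap.t_axis, indexing="ij")
    pd.DataFrame(
        {"x": xg.ravel(), "t": tg.ravel(), "value": srmap.values.ravel()}
    ).to_csv(path, index=False, float_format="%.17g")


def load_strain_rate_map_csv(path) -> StrainRateMap:
    import pandas as pd

    df = pd.read_csv(path)
    x = np.unique(df["x"].to_numpy())
    t = np.unique(df["t"].to_numpy())
    values = df["value"].to_numpy().reshape(x.size, t.size)
    return StrainRateMap(values, x, t)
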