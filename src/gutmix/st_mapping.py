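"""Spatiotemporal motility maps from intestine image sequences.

Ex-vivo recordings of the duodenum (monochrome, 5 frames/s, 0.13 mm/pixel)
are reduced to two maps:

- D map — local tube diameter over (x, t), from the thresholded
  silhouette: constrictions and dilatations along the segment.
- L map — longitudinal strain rate d(eps)/dt over (x, t): vascular-pattern
  texture is tracked between successive frames by windowed 1D normalised
  cross-correlation (with parabolic sub-pixel refinement), and the strain
  rate is the spatial gradient of the resulting frame-to-frame velocity.

Sign convention: positive strain rate = local lengthening (relaxation),
matching the map figures of the source recordings; the convention in the
literature is not consistent, so ``sign`` can flip it.

Recordings are screened before use: any diameter trough that propagates
monotonically along the segment flags peristalsis (such recordings are
excluded — the flow model assumes non-propagating activity), and the
L map must show persistent oscillatory activity throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pendular_synth import StrainRateMap

__all__ = [
    "DiameterMap",
    "DisplacementField",
    "ScreeningReport",
    "compute_diameter_map",
    "compute_displacement",
    "compute_strain_rate_map",
    "screen_recording",
]

logger = logging.getLogger(__name__)


@dataclass
class DiameterMap:
    """Local diameter (mm) on an (x, t) grid; NaN where no tube detected."""

    values: np.ndarray  # (nx, nt) mm
    x_axis: np.ndarray  # mm
    t_axis: np.ndarray  # s


@dataclass
class DisplacementField:
    """Frame-to-frame longitudinal displacement at window centres.

    ``values[i, j]`` is the displacement in pixels of the texture at
    window centre ``x_centres[i]`` between frames j and j+1; entries whose
    correlation peak fell below ``correlation_floor`` are NaN.
    """

    values: np.ndarray      # (n_windows, n_frames-1) px
    x_centres: np.ndarray   # px
    window: int
    correlation_floor: float
    valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.values)


def compute_diameter_map(
    images: np.ndarray,
    intensity_threshold: float | None = None,
    pixel_size_mm: float = 0.13,
    fps: float = 5.0,
) -> DiameterMap:
    """Diameter map from a (frames, rows, columns) image stack.

    Per column and frame, the diameter is the span between the outermost
    rows whose intensity exceeds the threshold (Otsu's threshold of the
    first frame by default), times the pixel size.  Columns with no
    detected silhouette yield NaN and are logged.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValueError("expected an image stack (frames, rows, columns)")
    if intensity_threshold is None:
        from skimage.filters import threshold_otsu

        intensity_threshold = float(threshold_otsu(images[0]))

    n_frames, n_rows, n_cols = images.shape
    values = np.full((n_cols, n_frames), np.nan)
    cols = np.arange(n_cols)
    n_missing = 0
    for j in range(n_frames):
        frame = images[j]
        mask = frame > intensity_threshold
        any_col = mask.any(axis=0)
        first = mask.argmax(axis=0)
        last = n_rows - 1 - mask[::-1].argmax(axis=0)
        span = (last - first + 1).astype(float)
        # sub-pixel refinement: the outermost silhouette rows may be only
        # partially covered by the tube (edge antialiasing); estimate
        # their coverage against the column's interior intensity and the
        # background level, and subtract the missing fractions
        below = frame[~mask]
        bg = float(np.median(below)) if below.size else 0.0
        interior = frame.max(axis=0)
        denom = np.maximum(interior - bg, 1e-12)
        cov_top = np.clip((frame[first, cols] - bg) / denom, 0.0, 1.0)
        cov_bot = np.clip((frame[last, cols] - bg) / denom, 0.0, 1.0)
        diam = (span - (1.0 - cov_top) - (1.0 - cov_bot)) * pixel_size_mm
        diam[~any_col] = np.nan
        n_missing += int((~any_col).sum())
        values[:, j] = diam
    if n_missing:
        logger.warning(
            "no silhouette detected in %d column-frames (of %d)",
            n_missing, n_cols * n_frames,
        )
    return DiameterMap(
        values=values,
        x_axis=np.arange(n_cols) * pixel_size_mm,
        t_axis=np.arange(n_frames) / fps,
    )


def compute_displacement(
    images: np.ndarray,
    window: int = 32,
    step: int = 8,
    correlation_floor: float = 0.5,
    band: tuple[int, int] | None = None,
) -> DisplacementField:
    """Frame-to-frame longitudinal displacement by windowed 1D NCC.

    The stack is collapsed to one longitudinal intensity profile per frame
    (mean over ``band`` rows, default the full frame — for real recordings
    pass the wall-adjacent strip carrying the vascular texture).  For each
    window centre, the displacement between frames t and t+1 is the argmax
    of the normalised cross-correlation, refined to sub-pixel accuracy by
    parabolic interpolation.  Peaks below ``correlation_floor`` give NaN.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] < 2:
        raise ValueError("need an image stack with at least two frames")
    if window < 16:
        raise ValueError("window must be at least 16 px")
    rows = slice(*band) if band is not None else slice(None)
    profiles = images[:, rows, :].mean(axis=1)  # (frames, columns)

    n_frames, n_cols = profiles.shape
    max_shift = window // 2 - 1
    centres = np.arange(window // 2 + max_shift,
                        n_cols - window // 2 - max_shift, step)
    values = np.full((centres.size, n_frames - 1), np.nan)
    for j in range(n_frames - 1):
        for i, cx in enumerate(centres):
            values[i, j], peak = _window_shift(
                profiles[j], profiles[j + 1], cx, window, max_shift)
            if peak < correlation_floor:
                values[i, j] = np.nan
    return DisplacementField(
        values=values, x_centres=centres.astype(float),
        window=window, correlation_floor=correlation_floor,
    )


def _window_shift(prev: np.ndarray, cur: np.ndarray, centre: int,
                  window: int, max_shift: int) -> tuple[float, float]:
    """NCC displacement of the window at ``centre`` between two profiles."""
    half = window // 2
    ref = prev[centre - half: centre + half]
    ref = ref - ref.mean()
    ref_norm = np.sqrt((ref**2).sum())
    lags = np.arange(-max_shift, max_shift + 1)
    corr = np.full(lags.size, -np.inf)
    for i, lag in enumerate(lags):
        lo = centre - half + lag
        hi = lo + window
        if lo < 0 or hi > cur.size:
            continue
        seg = cur[lo:hi]
        seg = seg - seg.mean()
        denom = ref_norm * np.sqrt((seg**2).sum())
        corr[i] = (ref * seg).sum() / denom if denom > 0 else 0.0
    k = int(np.argmax(corr))
    shift = float(lags[k])
    peak = float(corr[k])
    if 0 < k < corr.size - 1 and np.isfinite(corr[k - 1]) and np.isfinite(corr[k + 1]):
        denom = corr[k - 1] - 2 * corr[k] + corr[k + 1]
        if denom < 0:
            shift += 0.5 * (corr[k - 1] - corr[k + 1]) / denom
    return shift, peak


def compute_strain_rate_map(
    disp: DisplacementField,
    fps: float = 5.0,
    pixel_size_mm: float = 0.13,
    sign: float = 1.0,
    smooth_centres: float = 2.0,
) -> StrainRateMap:
    """Longitudinal strain rate from a displacement field.

    The strain rate is the spatial gradient (central differences over the
    window centres) of the inter-frame velocity: d(eps)/dt = d(disp)/dx *
    fps, dimensionless per second.  Sub-pixel tracking noise is amplified
    by the derivative, so the displacement field is Gaussian-smoothed
    along x (``smooth_centres`` centres; 0 disables) first.  Positive =
    lengthening by default; ``sign=-1`` flips the convention.  NaN
    displacements propagate.
    """
    if disp.values.shape[0] < 3:
        raise ValueError("need at least 3 window centres for a gradient")
    vals = disp.values
    if smooth_centres > 0:
        half = int(np.ceil(3 * smooth_centres))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / smooth_centres) ** 2)
        kern /= kern.sum()
        smoothed = np.full_like(vals, np.nan)
        finite = np.isfinite(vals)
        filled = np.where(finite, vals, 0.0)
        for j in range(vals.shape[1]):
            num = np.convolve(filled[:, j], kern, mode="same")
            den = np.convolve(finite[:, j].astype(float), kern, mode="same")
            with np.errstate(invalid="ignore"):
                smoothed[:, j] = np.where(den > 0.5, num / den, np.nan)
        vals = smoothed
    ddx = np.gradient(vals, disp.x_centres, axis=0)
    values = sign * ddx * fps
    x_m = disp.x_centres * pixel_size_mm * 1e-3
    t = (np.arange(disp.values.shape[1]) + 0.5) / fps
    return StrainRateMap(values=values, x_axis=x_m, t_axis=t)


@dataclass
class ScreeningReport:
    """Outcome of the peristalsis / activity-persistence screen."""

    peristalsis_detected: bool
    max_propagation_mm: float
    activity_fraction: float
    persistent: bool
    passed: bool
    details: dict = field(default_factory=dict)


def screen_recording(
    dmap: DiameterMap | None,
    lmap: StrainRateMap,
    propagation_threshold_mm: float = 10.0,
    constriction_depth: float = 0.1,
    activity_floor: float = 0.05,
    activity_window_s: float = 30.0,
    min_activity_fraction: float = 0.8,
) -> ScreeningReport:
    """Screen a recording for peristalsis and persistent pendular activity.

    Peristalsis: the position of the deepest diameter constriction is
    tracked over time (only frames whose constriction is at least
    ``constriction_depth`` of the local mean diameter count); the longest
    monotonic excursion of that position is compared against
    ``propagation_threshold_mm``.  Raising the threshold can only turn a
    failure into a pass, never the reverse.

    Persistence: the fraction of ``activity_window_s`` windows whose
    L-map oscillation amplitude (spatial-max RMS) exceeds
    ``activity_floor`` (1/s) must reach ``min_activity_fraction``.
    """
    max_prop = 0.0
    if dmap is not None and np.isfinite(dmap.values).any():
        mean_d = np.nanmean(dmap.values)
        trough_x = np.full(dmap.t_axis.size, np.nan)
        for j in range(dmap.t_axis.size):
            col = dmap.values[:, j]
            if not np.isfinite(col).any():
                continue
            i = np.nanargmin(col)
            if col[i] < (1.0 - constriction_depth) * mean_d:
                trough_x[j] = dmap.x_axis[i]
        # longest monotonic run of the trough position
        run_start = None
        direction = 0
        for j in range(1, dmap.t_axis.size):
            a, b = trough_x[j - 1], trough_x[j]
            if not (np.isfinite(a) and np.isfinite(b)) or b == a:
                run_start, direction = None, 0
                continue
            d = 1 if b > a else -1
            if run_start is None or d != direction:
                run_start, direction = j - 1, d
            excursion = abs(trough_x[j] - trough_x[run_start])
            max_prop = max(max_prop, float(excursion))
    peristalsis = max_prop > propagation_threshold_mm

    # activity persistence from the L map
    dt = np.diff(lmap.t_axis).mean() if lmap.t_axis.size > 1 else 1.0
    win = max(int(activity_window_s / dt), 1)
    nt = lmap.t_axis.size
    amps = []
    for start in range(0, nt, win):
        chunk = lmap.values[:, start:start + win]
        if chunk.size == 0:
            continue
        amps.append(np.nanmax(np.sqrt(np.nanmean(chunk**2, axis=1))))
    amps = np.asarray(amps)
    activity_fraction = float((amps > activity_floor).mean()) if amps.size else 0.0
    persistent = activity_fraction >= min_activity_fraction

    return ScreeningReport(
        peristalsis_detected=bool(peristalsis),
        max_propagation_mm=float(max_prop),
        activity_fraction=activity_fraction,
        persistent=bool(persistent),
        passed=bool(persistent and not peristalsis),
        details={"window_amplitudes": amps.tolist()},
    )
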