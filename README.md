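# gutmix

Mixing in the small intestine during **pendular activity** — spontaneous,
non-propagating longitudinal contractions — characterised the way reactor
engineers characterise any flow system: by the step-response
residence-time distribution (RTD) and its tanks-in-series description.

The package is aimed at gastrointestinal biomechanics and digesta-flow
modellers.  It provides, as one tested pipeline:

- a generator of synthetic pendular-activity **strain-rate maps**
  (3–5 contractile domains, 0.3–0.5 s⁻¹, 15-minute sequences) and of
  marker-textured intestine image sequences;
- **spatiotemporal mapping** of image sequences into diameter (D) and
  longitudinal strain-rate (L) maps by thresholded silhouettes and
  windowed cross-correlation, with peristalsis screening;
- a **lattice-Boltzmann flow solver** (D2Q9 TRT, Zou–He boundaries) for
  the 2D half-lumen driven tangentially by the strain-rate map, plus an
  exactly incompressible unsteady-Stokes channel solver used to drive
  the tracer at full pendular frequency;
- a **lattice-Boltzmann passive-tracer** (D2Q5 advection–diffusion)
  scheme with step injection and cup-mixing outflow extraction — the
  simulated ("CFD") RTD;
- the **tanks-in-series analysis**: the N-CSTR step response

  F(t) = 1 − e^(−Nt/τ) Σ_{k=0}^{N−1} (Nt/τ)^k / k!  = P(N, Nt/τ),

  where τ is reactor volume over flow rate, fitted by grid search over
  integer N ∈ [1, 100] with τ optimised per N, both data and model passed
  through the 1-minute collection filter that mimics per-minute effluent
  tubes.  N = 1 is a single stirred tank; N → ∞ approaches plug flow.

All physical defaults are the study conditions of the perfused rat
duodenum: 10 cm segment, 4 mm lumen, 0.16 mL/min, μ = 1 mPa·s,
D = 5×10⁻¹⁰ m²/s.

## Worked example

Fit a measured-style F curve (per-minute samples of C/C₀):

```python
import numpy as np
from gutmix import (apply_collection_filter, cstr_step_response,
                    fit_cstr, tau_from_geometry)

tau = tau_from_geometry(length=0.1, diameter=4e-3, flow_rate_ml_min=0.16)
t = np.arange(0.0, 1801.0, 1.0)                      # dense seconds
curve = apply_collection_filter(t, cstr_step_response(8, tau, t))
fit = fit_cstr(curve)
print(f"N = {fit.n_tanks}, tau = {fit.tau/60:.2f} min, R^2 = {fit.r_squared:.6f}")
```

prints

```
N = 8, tau = 7.85 min, R^2 = 1.000000
```

— the duodenal lumen (volume/flow ≈ 7.85 min) behaving as eight stirred
tanks in series, recovered exactly from its own minute-collected
response.  The near-plug-flow silicone-tube control (68 tanks,
τ ≈ 4.42 min from the 3 mm tube geometry) recovers the same way
(`analysis/02_reactor_bench.py`).

Running the full simulated study (`analysis/03_cfd_rtd.py`, a few
minutes) drives five synthetic pendular sequences through the coupled
flow + tracer model and prints, for the averaged curve:

```
Simulated RTD: best fit 8 stirred tanks in series (tau = 7.42 min, R^2 = 0.956);
baseline (no contractions) fits 8 tanks.
```

Eight tanks means strong axial dispersion: luminal transport during
pendular activity is nowhere near the 68-tank plug-flow control.  The
R² ≈ 0.96 (below the ≥0.98 of measured curves) reflects the flat-footed,
long-tailed advection-dominated shape of the purely macro-scale model —
consistent with such models underestimating peripheral mixing.
`analysis/04_dispersion_maps.py` renders the tracer isovalue panels and
quantifies the peripheral-vs-central front gains.

The `gutmix` command-line tool exposes the same steps
(`gutmix synth lmap`, `gutmix simulate`, `gutmix fit`, `gutmix compare`,
`gutmix pipeline`).

## Layout

- `src/gutmix/` — library: `pendular_synth`, `st_mapping`, `lbm_flow`,
  `channel_flow`, `tracer_lbm`, `rtd`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers of the study steps.
- `tests/` — pytest suite (unit, property and acceptance tests).
- `docs/methods.md` — the model, numerics, design choices and limits.
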