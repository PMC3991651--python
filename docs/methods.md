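# Methods

`gutmix` models luminal mixing in a perfused segment of proximal duodenum
during pendular activity — spontaneous, non-propagating longitudinal
contractions — and characterises the result the way reactor engineers
characterise any flow system: by the step-response residence-time
distribution (RTD) and its tanks-in-series description.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic test bed does and does not establish.

## Physical model

The lumen is a straight planar channel of length L = 10 cm whose
centreline is a symmetry axis; the computational domain is the half
channel of width h = 2 mm (half the 4 mm lumen).  This is a 2D Cartesian
description, not an axisymmetric one: the perfusion rate Q = 0.16 mL/min
enters only through the mean axial velocity U = Q / (πR²) ≈ 2.12×10⁻⁴
m/s.  The fluid is water-like (μ = 1 mPa·s, ρ = 10³ kg/m³), giving
Re ≈ 8×10⁻⁴ — deep creeping flow.  The tracer is methylene-blue-like with
D = 5×10⁻¹⁰ m²/s; the radial diffusion time h²/D ≈ 8000 s far exceeds the
mean residence time τ = V/Q ≈ 471 s, so transport is advection-dominated
(Péclet ≈ 10⁶ axially) and the no-contraction RTD is far from plug flow.

The wall is geometrically fixed (peristalsis is screened out of the
motility data by construction) and moves only tangentially, with
longitudinal velocity u_w(x, t) obtained by integrating the strain-rate
map from the oral end.  Both ends of the segment are cannulated, so the
spatial integral of the strain rate is forced to zero at every instant
and u_w vanishes at both ends.  Inlet: parabolic (Poiseuille) velocity
with mean U and dye concentration stepping from 0 to 1 at t = 0.
Outlet: zero pressure, zero diffusive flux.  The step-response F curve is
the flux-weighted (cup-mixing) outlet concentration — what drop-by-drop
collection into per-minute tubes measures — passed through a 1-minute
boxcar filter that mimics the collection tubes exactly; model curves are
filtered identically before any comparison or fit.

## Synthetic pendular activity

No deposited motility recordings exist, so the generator produces
strain-rate maps with the reported statistics: 3–5 contiguous spatial
domains, peak amplitude 0.3–0.5 s⁻¹, 15-minute sequences, five sequences
per study (seeds `seed+0..seed+4`).  Within a map, adjacent domains
oscillate in antiphase with cosine-tapered boundaries whose positions are
jittered per seed.  Three properties of recorded activity that a pure
standing tone lacks are modelled explicitly, because the observed
activity "waxes and wanes":

- per-domain frequency detuning (±5 % around the base frequency), so
  domains drift out of phase over minutes;
- random initial phases;
- a slow random amplitude envelope per domain (Gaussian-filtered noise,
  60 s correlation time, 35 % depth).

The oscillation frequency itself is not constrained by the available
data; the default is 0.5 Hz, consistent with rat duodenal slow-wave-paced
contraction rates, and is a configurable modelling choice.  The
zero-net-length invariant is enforced by subtracting the instantaneous
spatial mean, and the configured amplitude is imposed as the pointwise
maximum, so both map invariants hold by construction.

The image branch of the generator renders speckle-textured tube
silhouettes (0.13 mm/pixel, 5 frames/s, antialiased edges) whose texture
is advected by the map, providing a ground-truthed fixture for the
mapping stage: windowed 1D normalised cross-correlation with parabolic
sub-pixel refinement recovers imposed displacements to ~0.1 px and the
imposed strain-rate amplitude to within a few percent (the displacement
field is Gaussian-smoothed along x before differentiation; edge windows
carry the usual one-sided-window bias).

## Flow solvers

Two flow drivers exist, with distinct validity envelopes.

**D2Q9 lattice-Boltzmann** (module `lbm_flow`): two-relaxation-time
collision (magic product 3/16) with the He–Luo incompressible
equilibrium, Zou–He velocity inlet / pressure outlet, a Zou–He moving
tangential wall, and a mirror-image symmetry condition through the
centreline row.  Validated against plane Poiseuille (<1 % L2, with the
error falling under refinement), global mass conservation, creeping-flow
linearity, the closed-form uniformly-dragged channel, an independent
Crank–Nicolson Stokes-layer solve for an oscillating wall (Womersley
number ≈ 3.5), and quasi-steady lubrication profiles for slowly varying
wall velocity.

A weakly compressible lattice cannot, however, follow the 0.5 Hz
pendular drive in this geometry at any affordable time step: the
oscillating lubrication pressure field interacts with the lattice
pseudo-sound speed (c_s = 0.577·dx/dt ≈ 0.05 m/s at feasible dt) and
stores mass axially, producing spurious axial sloshing with
cross-section fluxes many times the perfusion flux — which breaks the
tracer's mean-residence identity ∫(1−F)dt = V/Q.  Restoring acoustic
compactness needs dt ≲ 10⁻⁴ s, i.e. millions of steps per 15-minute
sequence.

**Incompressible unsteady Stokes channel solver** (module
`channel_flow`, the default driver for production RTD runs): because the
lumen is long and thin (h/L = 0.02) and the wall moves only
tangentially, the axial momentum balance reduces per column to
∂u/∂t = −G(x,t)/ρ + ν ∂²u/∂y², with the pressure gradient G fixed at
every column and instant by the exact flux constraint ∫u dy = Uh, and
the radial velocity recovered from continuity.  Crank–Nicolson in time
with a prefactored Thomas solve per column; the constant-forcing
response is precomputed so the flux constraint costs one extra
superposition.  This resolves the Womersley layer exactly (validated
against the complex closed form to 0.4 % of the wall amplitude) and is
divergence-free by construction.  The two solvers agree to <5 % where
both are valid (slow oscillation).

## Tracer scheme

The tracer is a D2Q5 two-relaxation-time advection–diffusion lattice with
a linear-velocity equilibrium.  The odd (flux) eigenvalue carries the
physical diffusivity, which at these parameters is essentially
unresolved (lattice diffusivity ~3×10⁻⁵), so the odd relaxation sits at
the zero-diffusion margin and the free even eigenvalue decides
everything.  Empirically — and consistent with the TRT stability
literature — only two members of the family are usable at the wall-row
lattice velocity (~0.1): the magic-product member Λ = 1/4 and the BGK
member (equal eigenvalues).  The Λ = 1/4 member drags a slowly relaxing
concentration-deficit wake of length ≈ τ_even·u cells behind any front
(because Λ = 1/4 with τ_odd → ½ forces τ_even into the hundreds), which
biases the plateau and the apparent front position by several percent.
The BGK member transports fronts at exactly the fluid velocity with an
exact plateau and is the default (`ad_scheme="bgk"`; `"magic"` remains
selectable).  Its start-up wiggle at the initially one-cell-sharp dye
step is controlled by giving the inlet Dirichlet value a 30 s rise time
(`inlet_ramp_s`) — 6 % of τ, invisible after the 1-minute collection
filter.

Boundaries: anti-bounce-back Dirichlet at the inlet face (half a cell
upstream of the first column), zero-gradient outlet, halfway bounce-back
at the wall and the centreline.  The closed sides are exactly mass
conserving, and the mass budget (inlet face flux − last-interface flux −
interior change, all at population level) closes to round-off on every
run; the 0.5 % acceptance band is met with ~10 orders of margin.

Maximum principle: a central scheme advecting a front far sharper than
the lattice (grid Péclet ~10⁴) produces locally bounded wiggles; their
crest height is dt-converged and episodically reaches a few tens of
percent at the near-wall sharp layer without ever touching the outflow
curve.  A conservative rare-event limiter trims nodes outside
[−0.9·tol, 1+0.9·tol] (scheme tolerance tol = 0.2) and moves the clipped
mass into neighbouring nodes: on the worst sequence it relocates <1 % of
the injected mass and changes the F curve by <10⁻⁸.  Diagnostics report
the moved mass per run.

Validation: Gaussian-pulse variance growth 2Dt per axis and the erf
solution of the diffusing step, both within 2 % in a sealed box; the
zero-amplitude baseline curve against the closed-form laminar
(pure-advection) planar RTD; and grid-refinement consistency of the
baseline curve.

## RTD analysis

The tanks-in-series step response F(t) = P(N, Nt/τ) (regularised lower
incomplete gamma; equivalent to the truncated-exponential form but stable
at large N) is fitted by exhaustive search over integer N ∈ [1, 100]
with, for each N, the time constant optimised by bounded least squares —
a coarse log-spaced τ scan followed by local refinement, because the
least-squares valley in τ narrows like τ/√N and a plain line search can
stall on the flat shoulders.  The model is always evaluated through the
same 1-minute collection filter as the data (the filter and the model do
not commute; the recovery sweep fails if the raw model is used).  Ties in
R² break toward smaller N (parsimony).  Replicate curves are averaged
pointwise with n−1 standard deviations, and envelope comparisons flag
minute marks where a reference mean leaves the candidate mean ± 1 s.d.
(boundaries count as inside).  Experimental plateaus below 1 (dye
absorption in the mucus of real preparations) are fitted as-is by the
two-parameter model; no plateau scale is introduced by default.

Self-consistency anchors: the duodenal configuration (8 tanks,
τ = πR²L/Q ≈ 7.85 min) and the tube control (68 tanks, τ from the 3 mm
tube ≈ 4.42 min) are recovered exactly with R² > 0.999 from their own
filtered minute-sampled responses, as is every N in {1, 2, 4, 8, 16, 32,
68} with τ within 2 % of V/Q.

## Problem sizes

Production runs use the 500 × 10 grid (dx = dy = 0.2 mm) for 900 s with
dt chosen so the peak wall velocity stays at 0.1 lattice units
(≈ 1.5–2.5 ms; ~4–6×10⁵ steps per sequence, under a minute each on one
CPU).  The module test suite exercises the same code paths on half- and
quarter-length channels (125 × 5, 50 × 4) with shorter horizons, sizes
chosen so the whole suite runs in minutes; the acceptance suite runs the
five-sequence study at full production scale.

## Design choices where the design was open

- Planar half-channel with a symmetry axis, not an axisymmetric solver:
  fidelity to the 2D Cartesian description of the original model; the 3D
  flow rate enters through U only.
- Cup-mixing (flux-weighted) outlet concentration by default — what
  effluent collection measures; the area mean is available.
- Per-sequence domain counts and amplitudes are drawn uniformly from the
  reported ranges (3–5 domains, 0.3–0.5 s⁻¹) from the run seed.
- Sign convention: positive strain rate = local lengthening
  (relaxation); the literature is inconsistent on this and a flag flips
  it.
- Coordinates: x in metres from the oral end, time zero at the dye step.

## Limitations

- The motility is synthetic.  Passing tests show the pipeline recovers
  imposed statistics and known physics, not that real duodenal maps are
  reproduced; real recordings have spatial structure (boundary drift,
  asymmetric domains) the generator only caricatures.
- The simulated F curve is more advection-dominated (flat foot, long
  tail) than ex-vivo curves: the tanks-in-series family captures it with
  R² ≈ 0.95–0.96 rather than the ≥0.98 typical of measured curves.  This
  echoes the known behaviour of macro-scale models of this system, which
  underestimate peripheral (near-mucosa) mixing; the micro-scale
  mechanisms proposed for it (mucosal microfolding, mucin gel dynamics)
  are out of scope here.
- No dye absorption at the wall, so simulated F → 1; measured effluent
  plateaus below 1.
- 2D planar geometry, Newtonian fluid, passive one-way-coupled tracer,
  rigid straight wall (no radial contractions).
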