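# Methods

## Geometry: the keyhole-rod unit cell

The computational domain is one periodic unit of the enamel rod lattice: a
half-open square cross-section `[0, l) × [0, l)` with `l = 7.1 µm`, extruded
to `z ∈ [0, L]` with `L = 250 µm` (cell-centred uniform grid, default
64 × 64 × 250; spacings hx = hy ≈ 0.11 µm, hz = 1 µm).  The acid-exposed
face is z = 0.

The rod is a keyhole: a head disc of radius ρ = 2.4 µm centred at
(l/2, 0.62 l) plus an isosceles trapezoidal tail pointing toward the
periodic image of the neighbouring rod's head.  Published descriptions fix
only ρ and the sheath thickness; the tail dimensions and head position are
this package's editorial choices, exposed in the configuration (defaults:
tail width 0.99 l at the head-centre line tapering to half that over
0.65 l).  With these defaults the rod occupies roughly 60% of the
cross-section, the interrod ~30% and the sheath band the rest.

The sheath is rasterised as a band of width 0.22 µm straddling the rod
boundary (half inside, half outside), computed from the periodic signed
distance to the keyhole.  A configuration whose in-plane spacing cannot
resolve a positive sheath thickness is rejected rather than silently
approximated, so the minimum in-plane resolution at the default geometry is
nx = ny = 33.

## Crystallite orientation and the diffusivity tensor

Protons diffuse fast along the HAp c-axis and slowly across it.  Each cell
carries two tilt angles: Θ (rotation about x) and Ψ (about y); the global
tensor is

    D_G = R diag(d_trans, d_trans, d_fast) R^T,   R = R_y(Ψ) R_x(Θ),

implemented in the algebraically identical rank-one form
`d_trans I + (d_fast − d_trans) c c^T` with `c = R ẑ`, which preserves the
eigenvalues {d_fast, d_trans, d_trans} to machine precision.  Sheath cells
are isotropic at `d_sheath`.

The angle model is a cubic polynomial in the normalised boundary-distance
abscissa `u = clip(sd / w, −1, 1)`, where `sd` is the periodic signed
distance to the rod boundary and `w = 0.8 µm` a transition half-width.  The
default Θ cubic is the smoothstep `(π/2)(2 + 3u − u³)/4`: crystallites are
axial (Θ = 0) inside the head core and lie normal to the rod axis
(Θ = π/2) in the interrod plateau, tilting about x, i.e. toward the
head-to-tail direction — the common tilt direction reported for interrod
crystallites.  Ψ defaults to zero but is available for experiments.  A
plateau at π/2 rather than some intermediate angle follows from microscopy
of interrod crystallites, whose long axes lie approximately normal to the
rod; it also makes the tensor field exactly continuous across the periodic
seams.  Because `sd` is periodic, no angle discontinuity exists anywhere.

Calibrated transport defaults (µm²/s): `d_fast = 1.82e-2`,
`d_trans = 3.25e-5`, `d_sheath = 6.5e-7`.  Fully demineralised material is
isotropic at `d_demin`; the default equals `d_fast` — the dissolved zone
conducts at least as fast as the fastest mineral direction, but is not given
a much larger value, which would act as an unphysical superhighway and (see
below) make the stiff in-plane modes numerically intractable.  The test
suite carries the corresponding sensitivity check: once `d_demin` is well
above the mineral diffusivities, doubling it moves the front by < 5%.

An optional porosity correction `ε_t δ / τ` (transport porosity,
constrictivity, tortuosity; all default 1) rescales every local
diffusivity, and an Arrhenius helper `D_0 exp(−E_A/RT)` is provided for
temperature studies; neither is active by default.

## Transport and dissolution kinetics

Hydrogen ions obey `∂H/∂t = ∇·(D_G∇H) + k(H_c − H)` with `k = 2.0e-7 s⁻¹`
and apparent solubility `H_c = 10^−5.5 mol/L` (consistent with the
critical-pH picture; the value is a package default, exposed in the
configuration).  Initial pore fluid is near-neutral, H = 1e-14 mol/L
everywhere.

Scenario boundary conditions:

* axial — Dirichlet `H = 10^(−pH_acid)` on z = 0, Dirichlet `H = 1e-14` on
  z = L (a near-neutral deep sink), periodic in x and y;
* lateral — Dirichlet acid on y = 0, no-flux on y = l, periodic in x and z.

The phase parameter Φ (1 = pristine, 0 = dissolved) evolves by (i) the
dissolution trigger — exponential decay at `demin_rate = 1e-4 s⁻¹`
(emptying a cell in about a day, fast against three weeks of transport, so
the front is transport-limited) wherever local `H > 10^−5.5` in rod and
interrod cells — and (ii) the level-set stabilisation flux
`γ ∇·(ε∇Φ − Φ(1−Φ)n̂)` with `n̂ = ∇Φ/max(|∇Φ|, 1e-12 µm⁻¹)`.  Dissolution
is monotone: Φ is clipped to never increase, and sheath cells are inert
(acid-resistant protein-rich interface; only the sheath remains inside a
mature lesion).

Two stabilisation defaults deserve comment:

* `ε` defaults to the smallest grid spacing (the interface is kept about
  one cell thick);
* `γ` defaults to `0.01 d_fast / L`.  Under the monotonicity clip, a
  stronger stabilisation flux does net work against the interface: on a
  static sigmoid front with the acid trigger disabled, γ at the scale of
  the front speed erodes the interface by 4–7 µm over three weeks and
  leaves visible oscillations, while the default keeps the spurious drift
  below 0.5 µm.  This is precisely the "tune γ to avoid unwanted
  oscillations" regime of level-set stabilisation; the default errs on the
  weak side because the trigger already produces monotone fronts.

## Discretisation and integrators

Cell-centred finite volume on the uniform grid.  Normal fluxes use
harmonic-mean face diffusivities, which treat the five-orders-of-magnitude
sheath contrast without smearing; tensor cross terms use symmetrised
central differences; Dirichlet values sit on faces (half-cell flux), so all
cells remain unknowns.  Periodic axes wrap exactly.

**Cross-term flux limiter.**  The continuum tensor is positive definite
cell by cell, but the discrete mixed flux `d_ab` is damped only through the
harmonic-mean face diffusivities of the two coupled axes, which collapse
next to the sheath.  A mixed coefficient exceeding
`sqrt(min_a d_aa · min_b d_bb)` over the neighbouring cells is locally
undamped: it destabilises any affordable time integrator and violates the
discrete maximum principle.  The solver therefore clips `|d_ab|` to that
bound; the limiter is provably inactive wherever the field is smooth (the
oracle tests assert this on their fixtures).

**Time stepping.**  Default Δt = 6 h; the transport step is implicit, the
level-set stabilisation explicit with automatic CFL sub-cycling, the
trigger decay integrated exactly per step.  Two transport integrators share
the identical spatial operator:

* *direct* (≤ 30 000 cells): backward Euler with a cached SuperLU
  factorisation, refreshed when Δt, k, or the phase field (by more than
  0.02) changes.  Exact up to solver precision; used by every oracle and
  conservation test.
* *ADI* (larger grids): alternating-direction Lie splitting — the three
  axis operators are solved implicitly in sequence by batched (cyclic)
  Thomas sweeps, with the limited cross fluxes and the weak reaction source
  applied explicitly at the head of each sub-step.  Each implicit factor is
  an unconditional contraction, so the scheme is robust at any step; the
  first-order splitting bias is controlled by sub-stepping so that the
  per-axis stiffness `Δt·(w_lo + w_hi)` stays below `adi_rate_cap = 100`.
  At that cap, on a 36 × 36 × 20 reference problem, the split integrator
  agrees with exact backward Euler to ~2% in L2 and places the critical-pH
  isosurface within one cell; the test suite re-measures this agreement.

The central cross-term stencil is not monotone; small negative
concentration excursions (a few percent of the peak, next to strong
contrasts) are clipped to zero silently, larger ones are logged as
discretisation failures.

## Observables

* `mineral_profile`: M(z, t) = cross-section mean of Φ (midpoint rule),
  normalised so pristine = 1.
* `front_depth(profile, f)`: shallowest depth where M rises through `f`
  (linear interpolation; 0 if already above; axis length if never).
* `drop_depth`: steepest discrete rise of M with depth among interfaces
  whose shallow side has M < 0.5 — the cliff of complete interrod loss;
  ties break shallow; NaN when no lesion exists.
* `extract_front`: per transverse cell, the deepest Φ = 0.5 crossing.
* `classify_etch_pattern`: Type 1 if the mean front depth over rod cells
  exceeds the interrod mean by > 10% of the overall mean depth, Type 2 for
  the reverse, Indeterminate otherwise.  The 10% margin is an editorial
  threshold, exposed as an argument.
* `ph_sweep`: one full run per boundary pH at fixed exposure, tabulating
  `front_depth(0.8)` and fitting a least-squares line over a stated
  pH sub-range.
* `threshold_onset_ph`: bisection over the boundary pH for the onset of any
  Φ decrease; converges to the critical pH of the trigger (5.5) to the
  requested tolerance.

## Calibration

`rodemin.calibrate` fits any subset of {d_fast, d_trans, d_sheath, k} to an
observed M(z) profile at one time point: Nelder–Mead in log10-parameter
space (the parameters span five decades and the forward model is non-smooth
at cell-crossing events), bounds enforced inside the transform, RMSE over a
depth window (default 40–100 µm, the range where such observations are
trustworthy: shallower material is detached and unmeasured, deeper material
is pristine).  When `d_fast` is free, `d_demin` scales with it — the
dissolved zone is defined relative to the fastest mineral axis; holding it
fixed would let the dissolved zone relay acid at an unchanged rate and mask
the parameter being fitted.

Identifiability is configuration-dependent and the tests exercise both
sides.  A noiseless single-parameter fit recovers `d_fast` within 5%; a
two-parameter fit with 1% observation noise recovers `d_fast` and `d_trans`
within 20% on an interrod-rich cell where both leave large footprints on
M(z).  `d_sheath` is the fragile one: its footprint on an axial profile is
only a few depth points wide, so under 1% noise its fitted value can sit
tens of percent from the truth, and in a fit window observed before the
sheath has transmitted any acid it is exactly flat — a caveat the suite
asserts rather than hides.  Fitting the sheath conductance reliably would
need either a lateral-attack observation (sheath in series with the whole
transport path) or profiles at several times.

## Synthetic observations

`rodemin.fixtures` generates stand-in observed profiles emulating a
µCT-derived mineral-content curve: a double sigmoid with a sharp cliff
(default 40 µm) rising to pristine around a plateau depth (default 70 µm,
transition 20 µm), a floor at the sheath fraction (default 0.05), additive
Gaussian noise truncated to [0, 1], and truncation of depths above the
cliff to mimic the detached, unmeasurable surface zone.  Deterministic per
seed.  What these fixtures do *not* emulate: beam-hardening or segmentation
bias, lateral heterogeneity of real lesions, remineralisation, or any
multi-mineral chemistry — so passing calibration tests demonstrate
correctness of the inverse machinery, not field accuracy on real scans.

The module also carries the analytic erfc solution of 1-D semi-infinite
diffusion and a deliberately naive explicit finite-difference stepper
(`brute_force_step`, grids ≤ 10 × 10 × 20) used as an independent oracle
for the implicit solver.

## Behaviour of the default model, and limitations

Three properties of the default 21-day, pH 4.4 axial simulation deserve
explicit statement, because they dominate everything the model predicts:

1. **The lesion is deep and sink-limited.**  With the calibrated
   diffusivities, the rod head (axial diffusivity 1.82e-2 µm²/s over
   250 µm) approaches its quasi-steady profile within days, and the
   critical-pH isosurface of that profile sits at ~230 µm, set by the
   near-neutral Dirichlet sink on the far face — not by the microstructure.
2. **The cross-section floods laterally.**  The sheath
   (6.5e-7 µm²/s across 0.22 µm) transmits enough acid to bring the
   interrod over the critical concentration within ~a day wherever the head
   is above threshold, so interrod columns demineralise almost as deep as
   the head.  Consequently the abrupt-loss depth of the three-week profile
   is ~230 µm, the etch contrast between head and interrod is small at that
   time (the pattern classifier returns Indeterminate), and the pH sweep
   saturates near the sink for strong acids, flattening the pH–depth
   relation (the near-linear regime exists only while fronts are far from
   the sink).  A shallow (~40 µm) three-week cliff would require either a
   sheath conductance about forty times lower, or front kinetics
   substantially slower than the threshold-triggered decay used here — the
   front passes 40 µm after roughly one day, not three weeks (see the
   README example).
3. **The early-time behaviour is the physically interesting one.**  Within
   the first days the model does show the expected morphology: head ahead
   of interrod (Type 1 contrast), a cliff in M(z) in the tens of microns,
   and √t front growth; all desk-scale validation tests target this regime.

Other limitations: single-species chemistry (no Ca/P speciation, no
fluoride, no remineralisation); no mechanical detachment of the
low-mineral zone; the level-set stabilisation is deliberately weak (see γ
above); the front-tracking trigger is an explicit reconstruction — the
"true" interface velocity law of dissolving enamel is not representable as
a pure threshold decay, and any quantitative comparison with measured
lesion depths should treat `demin_rate`, the orientation polynomials and
the sheath conductance as calibration targets, which is what the
calibration module is for.

## Problem sizes used by the shipped runs

The acceptance script runs the 21-day axial scenario at 36 × 36 × 125
(~1.6e5 cells, the smallest in-plane resolution that resolves the 0.22 µm
sheath with margin) and the onset bisection on a 2 × 2 × 60 column; the
test suite uses 36 × 36 × 40 for the three-week run, 33 × 33 × 24 for the
pH sweep, columns and ≤ 12 × 12 × 50 grids elsewhere, chosen so the full
suite completes in well under half an hour on one core.
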