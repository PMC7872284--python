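# Methods

This note documents the model, the numerical schemes, the default
parameters and their rationale, and the known limitations of the package.
Units throughout: lengths in μm, times in s, pressures in MPa (so tensions
are MPa·μm = N/m); continuum densities are measured in units of the inactive
Bni1 pool ρ₀, stochastic densities in molecules/μm².

## Geometry

The cell outline is an axisymmetric generating curve parametrized by
arclength *s* from the projection apex, with *r* the local radius, *z* the
axial coordinate (decreasing tip → body), θ the angle between the outward
normal and the growth axis, and wall thickness *h*. The principal curvatures
are κ_s = ∂θ/∂s and κ_φ = sin θ / r, with the umbilic limit κ_φ → κ_s at
on-axis poles. Derivatives in *s* use fourth-order finite differences
(Fornberg weights), one-sided at open boundaries; at poles, all stencils act
on parity-extended (mirrored) data, and pole-point curvatures come from a
local odd polynomial fit of θ — a pointwise finite difference at the pole
has O(1/Δs) gain on node-level noise and destabilizes the Lagrangian apex
under the mechanics feedback, while the least-squares fit averages over
several nodes at the same formal accuracy.

Reparametrization resamples the curve at uniform arclength through cubic
splines of the parity-extended (r, z), recovers θ from the tangent, and
rescales the interpolated thickness so the total wall volume ∫2πrh ds is
preserved to machine precision.

Two canonical fixtures: a sphere of radius 2 μm (the pre-shmoo cell body)
and a pre-grown projection (hemispherical cap of radius 0.5 μm — projection
diameter ≈ 1 μm — a cylindrical tube, a tangent circular fillet, and a
2 μm spherical body closed at the rear pole; θ is continuous, κ_s jumps at
the arc junctions as for any arc-spline profile).

## Wall mechanics

The wall is a thin viscous shell inflated by constant turgor pressure. The
quasistatic force balance gives tensions algebraically from geometry; the
viscous constitutive law is inverted pointwise for the strain rates

    ε̇_s = (2σ_ss − σ_φφ)/(6μh),    ε̇_φ = (2σ_φφ − σ_ss)/(6μh).

The surface velocity field follows from the axisymmetric-shell kinematics

    ε̇_s = ∂u/∂s + v_n κ_s,    ε̇_φ = u cos θ / r + v_n κ_φ,

the unique closure consistent with both the static-parametrization and the
Lagrangian reading of the strain rates. Eliminating v_n yields a linear
first-order ODE in u, singular at poles (regularity forces u = 0 there).
On a closed curve the solution is defined only up to a rigid axial
translation (u = −sin θ, v_n = cos θ, strain-free); the discrete system is
solved by truncated-SVD least squares and the translation component is
removed by anchoring the solid-like wall region (μ > 10³ μ_min). For shapes
without a rigid region (the uniform-viscosity benchmarks) the minimal-norm
gauge of the least-squares solve is already the symmetric solution. Pole
values of v_n are obtained by even extrapolation from interior nodes, which
depend only on the algebraic κ_φ.

Wall-mass balance ∂_t(rh) + ∂_s(rhu) = rG is available in two discrete
forms. `update_thickness` is a finite-volume flux-form step on a static
grid whose discrete mass audit closes to machine precision. The integrators
instead advance wall volume on material cells — per-cell volume gains
G·area·dt, nodes move with (u ŝ + v_n n̂), and thickness is recovered after
the motion from the local area stretch — which is the same conservation law
in Lagrangian form and conserves the wall-volume total exactly through node
advection and regridding (a global rescale of the reinterpolated field
enforces the conserved total; the same transport carries the polarity
densities). The right-hand side r·G treats G as a thickness-deposition rate
(volume per area per time); the wall mass density then appears only in the
dimensionless mechanics group.

### Time stepping and stability

Explicit Lagrangian stepping of a pressurized viscous shell supports a
stiff, damped grid-scale mode (relaxation rate ≈ P/(6 μ h κ_φ³ l²) at
filtered grid scale l). The integrator (i) applies a Gaussian filter of 1.5
grid spacings to the velocity fields, (ii) bounds dt by the resulting
explicit stability limit, a CFL bound on tangential advection, and a 5% cap
on the per-step strain, and (iii) advances the geometry with a Heun
(predictor–corrector) step whose predictor also carries first-order-updated
thickness — without that, the corrector sees an undiluted wall and the
scheme degrades to first order. With it, the inflating uniform-viscosity
sphere tracks the closed form dR/dt = P R²/(12 μ h) (with h diluting as
R⁻²) to ~10⁻⁶ relative over a radius doubling at 80 nodes.

## Continuum polarity and the coupled integrator

Cdc42 and active Bni1 surface densities evolve by the linear
reaction–transport system given in the README; actin-cable density is
ρ_A = c_A ρ_B,a with c_A = 1 in scaled units (only the products c_A k_X and
c_A k_s are identifiable). The CWI activation rate k_CWI = A_CWI(ε̇_s+ε̇_φ)
is floored at zero (transiently negative numerical strain rates would give
an unphysical negative activation). The inactive Bni1 pool ρ₀ is uniform
and constant. λ_A in the viscosity profile is a fixed model parameter in
the continuum description (the decay length of actin from the tip); only
the stochastic growth coupling re-fits it from the sampled cable profile.

Surface diffusion uses a conservative finite-volume form of ∂_s(r ∂_s ρ)
with no-flux ends (pole faces carry zero area, so poles are regular), and
the chemistry is advanced by Strang splitting: exact 2×2 matrix-exponential
half-steps of the spatially-decoupled reaction block around a
Crank–Nicolson diffusion step. Both sub-steps are unconditionally stable
and discretely mass-conserving where the physics conserves mass (with
k_X = k_D = 0 the total Cdc42 is conserved to machine precision).

The mechanics is solved as an algebraic block each step (the method-of-lines
DAE structure: tensions, strain rates and velocities are instantaneous
functionals of the geometry), and geometry/thickness/densities are the
differential variables.

**Domain.** Continuum runs solve on the active region s ≤ λ_A √(ln 10⁶)
(≈ 3.7 λ_A), where the graded viscosity is below its solid-like cap; the
distal boundary is rigidly anchored (u = 0, h fixed) and no-flux for the
densities. Far from the tip the wall is effectively solid and the polarity
fields are dynamically irrelevant; keeping the full cell would only add a
large rigid annulus whose slow diffusive equilibration obscures the
tip-region dynamics.

**Steady states and classification.** Steadiness is evaluated in the tip
co-moving frame (profiles as functions of arclength from the current apex),
comparing scaled variables (lengths by (D/k_D)^1/2, time by 1/k_D, densities
by ρ₀, thickness by its mean) between snapshots; steady means all scaled
derivatives < 10⁻³. A run is *depolarized* if the final max ρ_C < 0.05 ρ₀
or the polarization index < 0.05, and *polarized_stable* if steady with the
cap within λ_A of the tip and index ≥ 0.5; both thresholds are configurable
artifacts of the classification, not model constants. The polarization
index uses a window of 2 λ_A around the cap. `scan_feedback` bisects
A_CWI between a depolarized and a polarized endpoint (geometric midpoints,
relative tolerance on the bracket).

## Stochastic model

The surface mesh has Ns equal-arclength bands, each split into Nphi
equal-area patches; bands touching an on-axis pole collapse to single polar
patches, so interior patches have 4 neighbors. Hop rates are D_mem/l² per
molecule per directed edge, with l the centroid distance (azimuthal:
2π r̄/Nphi). The cytoplasm is a single well-mixed compartment: cytosolic
diffusion is fast relative to the membrane dynamics at these scales, and
all reactions occur in membrane patches. Bimolecular membrane rates divide
by patch area, volume rates by the cytosol volume (standard RDME
conventions). The CWI nucleation channel distributes the monomer pool over
patches in proportion to area and multiplies by the local positive part of
the expansion rate, so its continuum limit is k_CWI ρ₀.

Sampling is an exact direct-method SSA over all channels. Channels
proportional to a cytosolic pool are factored (per-patch base rates times
the pool count), so pool-changing events need no global propensity rebuild;
running sums are refreshed every 4096 events against floating-point drift.
The event loop is numba-compiled and bit-reproducible for a given seed.
Activation is taken autocatalytic (GDP + GTP → 2 GTP at 0.2 μm²/s):
spontaneous symmetry breaking requires the positive feedback, and the
uniform state then ignites only where the membrane GDP density exceeds
k_inact/k_act = 5/μm².

### Copy-number regimes

Two regimes matter and they do not overlap:

* **Formation** (spontaneous symmetry breaking from a uniform state) needs
  total Cdc42 ≳ 1000–2000 on the 2 μm sphere, so that the uniform membrane
  GDP density crosses the ignition threshold; the symmetry-breaking
  experiments use 2000 Cdc42 / 500 actin (the package default is
  5000/1000, the order of magnitude of published yeast polarity
  compartment models).
* **Cap mobility** (the no-feedback cap wandering off the tip) requires
  small copy numbers (≈ 300–400 Cdc42), where a pre-formed, locally
  supercritical cap survives but diffuses over the surface. In the paper's
  full 3D setting delocalization is driven by geometry-dependent
  cytoplasmic gradients; a well-mixed cytosol cannot reproduce that
  mechanism, and stochastic cap wander at reduced copy numbers plays its
  role here. This is the main caveat when extrapolating the no-feedback
  results to real cells.

The fixed-geometry cap-fate experiments therefore run at 300 Cdc42 /
100 actin from a tip-concentrated initial cap, and the coupled growth runs
at 400/120 starting from a pre-formed tip cap (`init="tip_cap"`), with
`init="uniform"` available for formation-capable counts.

## Growth coupling

Each splitting step: (1) an SSA segment on the frozen geometry with a frozen
strain-rate field; (2) azimuthal (and segment-time) averaging of the cable
counts into ρ_A(s); (3) a λ_A fit — least squares of a·exp(−(s−s₀)²/λ²)
around the (smoothed) profile peak, half-maximum-width fallback when the
fit diverges, λ clipped to [0.25, 2] μm; (4) a mechanics advance of dt_mech
with G = k_s ρ_A and μ = μ₀ exp((s−c)²/λ_A²), internally substepped below
the explicit stability limit; (5) exact integer remapping of patch counts
to the new mesh by material band identity (ties toward the tip). The strain
field passed to the next SSA segment is the converged field of the new
shape sampled at band midpoints.

The soft-zone center c is the tip (c = 0, the form the graded-viscosity
profile takes when delivery is tip-anchored) whenever the CWI channel is
active — the feedback keeps nucleation, hence delivery, at the tip and
restores transient cap excursions. With the feedback off, nothing anchors
the delivery machinery, so the soft zone follows the cap (its position is
exponentially smoothed across segments, since wall properties respond to
time-integrated enzyme delivery); growth then chases the wandering cap and
no projection forms at any fixed site.

Before the first segment the strain field of the initial shape is computed
from the initial cable profile, so the CWI channel is live from t = 0 (the
wall is already under turgor).

Splitting cadence default is 1:1 (t_ssa_per_step = dt_mech = 50 s): the
sampler is cheap enough that biochemical time does not need subsampling,
and halving dt_mech changes the final tip displacement by a few percent
(3-seed averages).

## Default parameters

| quantity | default | rationale |
|---|---|---|
| P | 0.2 MPa | yeast turgor, ~atmospheres |
| h₀ | 0.1 μm | yeast wall thickness |
| μ₀ | 2800 MPa·s | tip expansion rate ≈ 6×10⁻⁵ s⁻¹: hours-scale growth, ≪ molecular rates |
| λ_A | 0.5 μm | actin decay length ≈ tube radius (projection diameter ~1 μm) |
| k_s (continuum) | 10⁻⁶ μm/s per ρ₀ | steady tip thickness slightly below h₀ (slight tip thinning) |
| k_s (stochastic) | 7×10⁻⁸ μm/s per μm⁻² | same balance at typical cap cable densities (~85 μm⁻²) |
| D | 0.04 μm²/s | cap length scale (D/k_D)^1/2 ≈ 0.45 μm |
| k_D, k_I, k_X | 0.2 s⁻¹ | seconds-scale membrane turnover |
| k_R | 0.03 s⁻¹ | loop gain k_R k_X/(k_I k_D) = 0.15 < 1: uniform state decays without feedback |
| A_CWI (continuum) | 5000 | well above the threshold A* ≈ 360 of this parameter set |
| β₁ | 0.05 μm³/s | cable delivery ≫ direct binding at a cap: winner-take-all regime |
| A_CWI (stochastic) | 2×10⁶ | CWI nucleation at the tip comparable to cable turnover at the growth-scale strain rates |
| printed rates | β₂, β₃, k_act, k_inact, A_on, A_off, D_mem | literature values quoted in the README |

The kinetic ratios and index thresholds were calibrated once so that both
qualitative regimes (depolarization without feedback, stable tip
polarization with feedback) exist and are detectable by the index
definitions; they are model defaults, all exposed in configuration.

## What the synthetic conditions do and do not show

The generator-side choices emulate: realistic cell and projection
dimensions; the separation between molecular (seconds) and growth (hours)
timescales; literature point values for the stochastic rate constants; and
copy numbers in the published range (with the reduced-copy caveat above).
They do not emulate: cytoplasmic diffusion gradients (well-mixed cytosol);
3D non-axisymmetric shapes (an off-axis cap appears as an annulus in the
azimuthal average, so the axisymmetric description is only faithful while
the cap is at or near the tip — the regime of interest); elastic/plastic
wall rheology (pure viscous limit); or pheromone-gradient steering. Passing
tests therefore demonstrate the internal consistency of the
mechanochemical feedback mechanism, not a quantitative fit to any
particular measured cell.

## Numerical edge cases

* All-zero actin profile → growth arrested (zero strain field), flagged.
* Flat cable profile → λ fit flagged as fallback (half-max width).
* κ_φ ≤ 0 anywhere → mechanics error (geometry outside model validity).
* Thickness driven non-positive → step-size error; the adaptive bounds
  prevent this in practice.
* Classification ties (steady but weakly polarized) → labeled depolarized
  with a warning flag.
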