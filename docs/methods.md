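# Methods

`dissectsim` simulates false-lumen thrombosis (FLT) in an idealized type B
aortic dissection as a two-dimensional, desk-scale analog: pulsatile
non-Newtonian channel flow through a true lumen (TL) and a false lumen (FL)
separated by a thin, mobile intimal flap with an entry and a re-entry tear,
two-way coupled to a four-species shear-driven thrombosis model.  This note
records the model, its assumptions, the numerical choices, and what the
reduced setting can and cannot show.

## Geometry: the planar two-channel analog

The 3D tube-in-tube dissection is reduced to a plane: lumen diameters become
channel widths (TL 19.4 mm, FL 23 mm), the flap is a 0.8 mm strip, the two
tears are 10 mm axial openings in the strip, and the FL is closed at both
extremities.  Axial dimensions are not fixed by the geometry's source
(dissected length, tear positions, extensions); the defaults — 200 mm
dissected length, tears centred 25 mm from each FL extremity, 40 mm inlet
and outlet extensions — are explicit configuration parameters.  All geometry
is specified in mm and converted once to metres at mesh build.

The mesh is a deterministic masked-structured triangulation: a tensor grid
aligned with every geometric feature line, with quads in the fluid region
split into right triangles.  Boundary facets are discovered topologically
and tagged (`inlet`, `tl_outlet`, `fl_endwall`, `outer_wall`,
`flap_tl_side`, `flap_fl_side`, `tear_edge`).  The logical structure gives
each wall node a wall-normal three-node stencil (used for wall shear
recovery) and each node a band coordinate (used for ALE motion).

## Hemodynamics

Blood: incompressible, density 1060 kg/m³, Quemada shear-thinning viscosity
at 45% hematocrit.  The Quemada parameter set (plasma viscosity 1.2 mPa·s,
k₀ = 4.33, k_∞ = 2.07, γ̇_c = 1.88 s⁻¹) is the standard whole-blood
parameterization; its high-shear asymptote is ≈ 4.2 mPa·s.  A constant
viscosity override exists for verification runs.  A floor of 10⁻¹² s⁻¹
regularizes √γ̇ at zero shear; it is kept tiny because the zero-shear
Quemada factor is near-critical at H = 0.45 and a larger floor visibly
shifts μ(0).

The momentum balance includes the thrombus resistance as a Brinkman-type
sink, −k_M·BP²/(BP² + BP_t²)·u with k_M = 10⁷ kg m⁻³ s⁻¹ and
BP_t = 20 nmol/L, so thrombosed regions (BP ≫ BP_t) behave as a porous
plug that brings the local velocity down by the ratio k_M/(ρ/dt) per step.

Discretization: P1 triangles, incremental pressure-correction projection.
Viscous terms and the (stiff) Brinkman sink are implicit — the sink as a
lumped nodal coefficient, so the velocity system stays one scalar matrix
shared by both components; convection is explicit with a streamline-only
upwind diffusion ν_sd = ½|u−w|h treated implicitly.  That term (a) vanishes
identically in developed channel flow, so the Poiseuille/Womersley/Brinkman
verification sees the clean scheme, and (b) renders the explicit central
advection von-Neumann stable for advective CFL ≤ 1.  First order in time,
second order in space.  A `stabilize=False` mode drops the streamline term
for diffusion-dominated verification runs and enables factorization
caching.

Boundaries: a flat pulsatile velocity profile at the inlet; a three-element
Windkessel pressure (exact exponential update of C·dP/dt = Q − P/R_p, then
P = P_wk + Q·R_c) at the TL outlet; no-slip elsewhere, with wall velocity
following the mesh (the closed FL end is an ordinary no-slip wall).  The
inlet waveform shape is a documented Fourier-series construction (1.02 Hz,
one systolic peak ≈ 4× mean, brief early-diastolic reverse flow); the mean
inlet velocity default 0.09 m/s follows from matching the stated mean
Reynolds number (≈ 450) at the TL width with blood viscosity.  Windkessel
defaults (R_p = 7.2×10⁶, R_c = 4×10⁵ Pa·s/m², C = 2×10⁻⁷ m²/Pa, per unit
depth) put the outlet pressure in a physiological 80–120 mmHg-like band at
that mean flow.  Both waveform and Windkessel values are honest
placeholders for inputs the source literature does not print, and are fully
configurable.

Wall shear stress is recovered per facet by one-sided quadratic
extrapolation of the tangential velocity along the precomputed wall-normal
stencils — exact for parabolic profiles, hence the 6μU/W channel check
passes at second order.  TAWSS accumulates the rectified WSS with a
configurable quadrature cadence (default every 5 steps) and is published at
cycle boundaries.

## Thrombosis model

Four species: resting platelets RP and activated platelets AP (relative
units, advected and diffusing), coagulant C (nmol/L, diffusing only — never
advected — with shear-gated diffusivity D_C = 10⁻⁸·φ_γ̇ m²/s), and bound
platelets BP (nmol/L, immobile; BP is the thrombus).  Sources:

    S_RP = k_RP [AP][RP]                       k_RP = −0.15 s⁻¹
    S_AP = k_AP [AP][RP]                       k_AP = 3.0 s⁻¹
    S_C  = k_C1 φ_C(BP)[AP] + k_C2 φ_C(C)[AP](1−φ_γ̇)
                                               k_C1 = 16, k_C2 = −6 nmol L⁻¹ s⁻¹
    S_BP = k_BP φ_BP(AP,C) φ_γ̇ [AP]           k_BP = 12 nmol L⁻¹ s⁻¹

with switches φ(x) = x²/(x² + x_t²) (AP_t = 15, C_t = 10 nmol/L,
BP_t = 20 nmol/L) and the shear switch φ_γ̇ = γ̇_t²/(γ̇² + γ̇_t²),
γ̇_t = 50 s⁻¹.  The shear switch is implemented in this dimensionally
consistent quadratic form (half-point exactly at γ̇_t); the literal
mixed-units variant with a linear γ̇ in the denominator is available as
`literal_shear_switch` for sensitivity checks.  The k_C1 term makes the
thrombus front self-propagating: C is produced inside established thrombus,
diffuses ahead of the front, and licenses BP deposition there.

Boundary conditions: RP and AP are held at a relative concentration of 2 on
all walls and at 1 at the inflow (fresh blood); BP has zero flux.  C
receives an inward wall flux of magnitude k_c_wall = 16 on facets whose
previous-cycle TAWSS is below 0.15 Pa while the local BP is still below
BP_t, and zero otherwise.  As printed, the flux constant's units
(nmol L⁻¹ m⁻¹ s⁻¹) do not close dimensionally against D_eff·∂C/∂n; the
package applies the value 16 directly as the Neumann datum of the 2D weak
form.  Near active walls C therefore rises quickly past C_t — the gating
behaviour the model requires — and saturates its switches; its absolute
magnitude in active wall cells is not physically meaningful.  During the
first cycle no previous-cycle TAWSS exists and the flux is disabled
(TAWSS treated as +∞), approximating the long flow-only preconditioning
protocol at desk scale; the number of flow-only pre-cycles is configurable
(default 3).

Transport: RP/AP advance by one-step Taylor-Galerkin (Lax-Wendroff FEM)
advection with consistent mass — chosen for its third-order phase accuracy,
which keeps dispersive ripples (and hence positivity clipping) at the
10⁻⁴ level — sub-stepped under a directional CFL cap of 0.4 (the mesh is
strongly anisotropic in the flap band), plus explicit diffusion.  C
diffuses explicitly (its diffusivity keeps the explicit limit at seconds).
Reactions are integrated nodally by sub-stepped RK4 after transport
(operator splitting).  Negativity from dispersive ripples is clipped with
a mass-conserving rescale and logged; BP is non-decreasing by construction
(S_BP ≥ 0, no lysis) and guarded.

The thrombus indicator is BP ≥ BP_t — the only BP threshold in the model,
shared with the momentum sink — and "volume" is indicator area × 1 m unit
depth, reported in cm³ for interface parity.  The FL-restricted volume
fraction is the primary comparative metric; the global volume trace is also
recorded (at marginal TL wall shear it can include thin TL wall layers).

## Mobile flap

The flap is a quasi-static pressure-loaded Euler-Bernoulli beam clamped at
the dissection ends, pinned (zero displacement, zero load) over the tear
gaps, with per-unit-depth stiffness E·t³/12 (presets: flexible 6.75 MPa,
stiffer 60 MPa, rigid).  Two reduced-order corrections make the planar beam
a usable stand-in for the 3D circumferentially attached flap:

* **Winkler foundation.** A per-unit-depth beam at these moduli is ~10⁴×
  softer than the real flap, whose restoring force comes mostly from
  bending across its circumferential attachment.  A foundation term
  k_s = 384·E·I/b⁴ (plate bending across the transverse span, b = FL
  width; ≈ 7×10⁵ Pa/m for the flexible preset) restores that stiffness at
  a physically motivated, E-proportional scale.  It defaults on in coupled
  runs and off in `solve_flap` itself, so the classical clamped-beam
  verification is untouched.
* **Coupling relaxation.** The transmural load ΔP(x) = P_TL − P_FL sampled
  on the flap faces is low-pass filtered (τ = T/8) before the beam solve;
  the displacement is under-relaxed (default 0.5) and its per-step
  increment limited to ¼ of the smallest cell.  Without these the
  partitioned quasi-static coupling is an added-mass limit cycle.
* A displacement cap (40% of the narrower lumen) prevents lumen pinch-off;
  the capped quantity is the quasi-static target.

Flap inertia and damping are neglected (natural frequency far above the
1.02 Hz forcing).  Outer walls are rigid.  Mesh motion is an analytic ALE
column stretch in delta form (TL stretches by f·w, flap band translates by
w, FL by (1−f)·w, with f the band coordinate): exactly identity at zero
displacement, inversion-free under the cap, with mesh velocity Δx/dt fed to
the ALE convection of both flow and species.

## Orchestration

Per step: Windkessel update from the current outlet flux → flap load,
beam solve, mesh move → flow step (with the momentum sink) → species step →
ledger accumulation.  Cycle boundaries publish TAWSS and cycle averages,
append the volume trace, write the manifest atomically, and optionally
checkpoint (npz with the config hash).  A run terminates after the
configured cycles or when per-cycle FL thrombus growth falls below 0.1% of
the FL volume.  A diverging flow step is retried at dt/2 (up to three
halvings).  The physics path contains no random numbers; identical configs
give identical trajectories, and a checkpoint restart is bitwise identical.

Default run control: 2000 steps/cycle at full scale; the mini
(desk-scale) configuration uses ~3k cells and 600 steps/cycle, which keeps
the advective CFL below 1 at the default waveform.  The verification suite
runs each oracle at the coarsest resolution that cleanly meets its stated
tolerance (e.g. 20–40 cells across a channel).

## What the desk-scale analog shows — and what it does not

The package preserves every model constant and every mechanism (shear
gating, TAWSS-gated coagulant wall flux, self-propagating front, Brinkman
flow hindrance, stiffness-modulated flap motion).  It does not reproduce
3D magnitudes, and at desk scale some qualitative 3D patterns change —
the coupled-run tests assert the target patterns and report these
divergences as failures rather than hiding them:

* **Growth phases.** The FL volume trace shows the expected time-lag,
  accelerated and plateau phases, with growth stopping at the 0.1%/cycle
  criterion.
* **Initiation and patency.** Deposition begins in the stagnant FL end
  pockets (both extremities ahead of the axial middle), as expected.  The
  axial mid-FL does *not* stay patent: plane-channel wall shear at the
  matched mean Reynolds number sits below the 0.15 Pa TAWSS gate along
  most of the FL corridor, whereas the 3D aorta keeps its middle section
  above the gate through jet impingement and secondary flows.  Thin
  thrombus layers can also appear along marginal TL walls for the same
  reason.
* **Flap-stiffness ordering.** A mobile flap raises flap-face wall shear
  above the TAWSS gate and suppresses deposition — the correct early-phase
  direction — but the late-phase enhancement that eventually makes the
  compliant-flap thrombus largest in 3D (vortex-driven transport of
  activated platelets) does not materialize here, because AP saturates
  domain-wide in the planar analog.  At desk scale the compliant flap
  therefore ends with the *smallest* thrombus, and the transmural pressure
  difference grows (rigid outer walls) rather than decaying as the FL
  seals, so flap excursion does not diminish after half-thrombosis.

Flap excursions are sub-millimetre fractions of the cap rather than the 3D
values.  Comparative runs remain useful precisely because these couplings
are mechanistic and inspectable; the test suite documents which directional
claims survive the 2D reduction and which do not.

## Verification summary

All expected values in the test suite are computed from independent
oracles: closed-form Poiseuille/Brinkman/Womersley solutions, the heat
kernel, translated Gaussians, a high-accuracy ODE integration of the
reaction kinetics, the classical clamped-beam deflection, eigen-analysis of
constructed velocity-gradient tensors, and hand-built fields for the
bookkeeping operations.  Structural invariants (switch bounds, BP
monotonicity, cascade non-self-start, mass balance, mesh validity under
ALE) are asserted both in unit tests and in-run.
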