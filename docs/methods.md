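# Methods

`graftflow` re-creates, at desk scale, a patient-specific hemodynamics
workflow for assessing thrombosis risk of stent grafts (endografts) in the
superficial femoral artery (SFA): duplex-derived inflow, tuned lumped
outflow models, a pulsatile incompressible flow simulation in the femoral
bifurcation, and time-averaged wall shear stress (TAWSS) mapping with a
virtual-angioplasty what-if. This note documents the models, their
assumptions, the numerical choices, and what the bundled synthetic cases
do and do not represent.

## Physical model

Blood is treated as an incompressible Newtonian fluid (density
ρ = 1060 kg/m³, dynamic viscosity μ = 3.5 mPa·s by default; optionally
derived from hematocrit H via μ = μ_plasma(1 + 2.5H + 7.35H²) with
μ_plasma = 1.2 mPa·s — a quadratic suspension relation anchored at the
Einstein dilute limit, chosen because it is monotone, matches the usual
3–4 mPa·s whole-blood range at physiological H, and is configurable).
Vessel walls are rigid and no-slip. Both simplifications (Newtonian
rheology, rigid walls) bias TAWSS magnitudes by of order 5–10% but are
not expected to move the *location* of low-shear regions, which is the
quantity of clinical interest here.

The domain is a two-dimensional planar analogue of the common femoral
artery (CFA) bifurcating into SFA and deep femoral artery (DFA). This is
a deliberate scope reduction from 3D patient lumens: it preserves the
mechanics that generate low TAWSS — flow division at the bifurcation
apex, post-stenotic jets and separation pockets, absence of reverse-phase
washout — at a cost of a few CPU-minutes per case instead of cluster
hours. Quantities that depend on secondary (out-of-plane, helical) flow
are outside the model.

### Geometry

Each vessel is a straight centerline with a smoothly varying half-width
w(s); s is arc length from the inlet plane (CFA) or from the junction
origin (daughters). Lesions are cosine bumps, C¹ at their shoulders so
they introduce no artificial shear singularities:

* stenosis: w(s) = w₀·(1 − severity·bump(s)) — severity is the fractional
  reduction of local cross-section, so a severity-0.5 lesion is a
  "50%-area" stenosis in the planar reading of area;
* widening: the same bump with opposite sign (patch-angioplasty bulges,
  widened graft-entry segments).

An endograft is an annotation of a wall interval (its luminal surface is
modeled smooth; strut-scale TAWSS fluctuations are ~0.05 Pa and below the
contrasts of interest). Virtual angioplasty ("cylindrical inflation")
restores an interval to nominal caliber with C¹ blends at the interval
ends; it is recorded declaratively on the geometry, which makes it
idempotent and non-mutating.

No patient lumen dimensions were available, so the default calibers are
textbook values: CFA 4 mm, SFA 3 mm, DFA 2.5 mm (half-widths), with the
DFA leaving at −40° and the SFA nearly continuing the CFA axis (+12°).

### Boundary conditions

Duplex ultrasound measures centerline velocity. For fully developed
pulsatile flow, centerline velocity and volumetric flow are related
harmonic-by-harmonic through the Womersley number α = R√(ω/ν); the
package implements the circular-tube relation (used to convert
measurements, since vessels are round) and the plane-channel relation
(used for the 2D solver's inlet profile and for verification). The
steady components use the Poiseuille ratios πR²/2 and (2/3)·2a.

Volumetric (m³/s) flows are mapped to the planar solver's per-unit-depth
flows (m²/s) by one global reference depth D = πR²_CFA/(2a_CFA) = πR_CFA/2,
chosen to preserve the CFA mean velocity; using a single depth for all
three branches keeps the mass budget consistent. Daughter-branch
velocities are correspondingly somewhat lower in the analogue than in a
tube of the same caliber — shear magnitudes inherit this compression, and
only contrasts between cases (not absolute Pa values) should be read
clinically.

Each outlet carries a 3-element Windkessel: C·dP_d/dt = Q − (P_d−P_ref)/R_d
with outlet pressure P = P_d + R_p·Q and impedance
Z(ω) = R_p + R_d/(1 + iωR_dC). Tuning to measured branch flows is
two-stage:

1. analytic initialization — total resistance from the mean-pressure /
   mean-flow balance (default mean perfusion pressure 100 mmHg, P_ref = 0),
   R_p:R_d = 0.09:0.91 and R_dC = T/3 (conventional peripheral values);
2. Nelder–Mead refinement in log-parameter space against the target
   outlet waveforms, using a 0D surrogate of the bifurcation (per-branch
   lubrication resistance ∫3μ/(2w³)ds and inertance ∫ρ/(2w)ds in series
   with each Windkessel; harmonic-wise junction split).

Two regularizers make the refinement well-posed: the implied mean
perfusion pressure is penalized against its target (the flow split alone
is invariant under a common rescaling of both outlets), and a weak
quadratic pull toward the initialization constrains the weakly identified
R_p:R_d split and compliance. Measured branch flows rarely sum to the
inlet flow (insonation error, deep-branch overestimation); targets are
renormalized to the inlet mean while preserving the measured split, and
the factor is reported.

### Duplex waveform synthesis

Since no waveform recordings are distributable, the generator produces
the two canonical femoral morphologies. Triphasic: three Gaussian lobes
(forward systolic peak of height PSV at 0.12T, reverse lobe of depth
reverse_fraction·PSV at 0.30T, late forward wave of 0.18·PSV at 0.55T;
widths 0.045/0.05/0.09·T). Monophasic (tardus-parvus): a broad forward
lobe at 0.20T (width 0.10T) over a sustained diastolic baseline of
0.05·PSV, everywhere non-negative. Optional additive Gaussian sample
noise is seed-controlled. These templates control peak, mean and
pulsatility independently, which is what the tests need; they do not
reproduce spectral broadening or beat-to-beat variability of real duplex.

## Flow solver

Equal-order P1–P1 finite elements on unstructured triangle meshes with
Brezzi–Pitkäranta pressure stabilization (τ_K = γ h_K²/(12μ), γ = 1;
the dt-independent scaling avoids the small-time-step pressure
instability of τ ∝ Δt variants). Time stepping: Crank–Nicolson for the
viscous term, explicit second-order Adams–Bashforth for the
skew-symmetric (energy-neutral) convection form, pressure implicit. The
proximal Windkessel resistance couples implicitly through a rank-one
outlet boundary matrix; the distal pressure ODE advances by the
trapezoidal rule using the just-computed outlet flux. The system matrix
is constant over a run: one sparse LU factorization, one back-substitution
per step.

* Time step: the target Δt (default T/1000) is reduced to satisfy the
  advective CFL limit of the explicit convection scheme, using a
  conservative velocity estimate from the inlet waveform and the minimum
  lumen width, and rounded to an integer number of steps per cycle.
* Backflow: femoral waveforms drive reverse flow through the outlets
  every cycle; outlets carry convective backflow penalization
  −βρ(u·n)₋u with β = 0.2, treated explicitly.
* Startup: fluid at rest, inlet ramped over the first half cycle, distal
  Windkessel pressures warm-started from the mean-flow estimate.
* Periodicity: the run stops at the first cycle whose outlet flow
  waveforms change by less than the tolerance in relative L2 against the
  previous cycle (the first cycle is compared against rest). Separated
  pulsatile flow on coarse meshes retains a ~2–4% cycle-to-cycle
  variability, so the coarse profile uses a 4% tolerance; oracle cases
  converge to 10⁻⁴.
* Conservation: with the stabilized P1–P1 pair the global flux balance
  |Q_in − ΣQ_out| holds to solver precision at every step (the
  stabilization term annihilates constant pressure test functions); the
  measured residual is reported with every run.

Meshing is lattice-Delaunay: the tagged boundary polyline is resampled at
the target edge length, interior points come from a hexagonal lattice
(plus a fixed "guard" row inside each boundary edge that keeps the
triangulation from skipping collinear cap runs), triangles outside the
domain are discarded (slivers filtered by an area/edge² cut), and
interior nodes are relaxed by Laplacian passes. The target edge length is
halved inside lesions and for 6 mm past their distal shoulder, where the
post-stenotic jet and its separation pocket live. Boundary tags
partition the boundary by construction; wall nodes carry their vessel,
side and arc-length coordinates.

### Wall shear extraction

Wall shear is recovered by the variational (consistent-flux) method: the
unconstrained momentum residual at wall nodes equals the weighted
boundary traction, and a 1D wall mass-matrix solve yields nodal
tractions. This is superconvergent compared with evaluating P1 gradients
(which are only O(h) at walls). One subtlety matters at physiological
pressures: the recovered traction contains −p·n, and on a faceted curved
wall the discrete normal direction is ambiguous at O(h·curvature), so
even milliradians of direction error would leak tens of Pa of pressure
into the "shear". The discrete pressure flux ∮φᵢ p_h n ds is therefore
subtracted edge-wise (it is exactly computable), leaving the purely
viscous traction; its component along the downstream wall tangent is the
signed shear. Wall nodes touching inlet/outlet caps are excluded (their
residual absorbs cap fluxes). Verified against the steady channel:
max deviation from 6μU/H below 2% at the default resolution (h = a/8).

TAWSS is the cycle average of |τ| (time-average of the magnitude, the
standard definition), computed by the periodic trapezoidal rule over the
~200 uniformly stored steps of the final cycle (integration error on a
sine-wave check ≪ 0.1%). "Area below threshold" is realized as wall
arc-length fraction, per named segment and overall; per-segment minima
and the global minimum location are reported. Thresholds default to
0.4 / 0.15 / 0.05 Pa — respectively the proatherogenic-activation level
and two levels reported around thrombosing grafts.

## Verification

* Womersley conversion: tube and channel flow/centerline ratios agree
  with numerical quadrature of the closed-form profiles to <10⁻⁶ over
  α ∈ {0.1, 1, 4.14, 10}; steady limits are exact.
* Windkessel: the trapezoidal periodic response matches the phasor
  solution to <10⁻⁶ at 8192 samples/cycle; the steady response
  P − P_ref = Q(R_p+R_d) is exact.
* Tuning: parameters regenerated from surrogate-produced flows recover
  the mean flow split within 1% and total resistances within 5%.
* Solver: steady channel wall shear within 2% of 6μU/H; oscillatory
  channel (α = 2.8, linear regime) velocity L2 error 1.4% at the default
  resolution with an observed convergence rate ≈ 2.0 over the coarse-to-
  default refinement (h and Δt halved together). At finer resolutions
  the error keeps falling (×3 per refinement) but enters a mixed regime
  where a small non-smooth component (outlet corner) degrades the
  *observed* rate; convergence is therefore quoted over the refinement
  ending at the default resolution. The oscillatory oracle runs at a
  modest amplitude because at physiological amplitudes the error is
  dominated by convective contamination entering through the open outlet
  during the reverse phase — a boundary-condition effect, not a
  discretization property.
* Conservation, Stokes-regime linearity, and TAWSS threshold-fraction
  monotonicity are asserted on every relevant run or as property tests.

## Bundled analogue cases

Two cases define the study conditions (see `graftflow.fixtures`):

* control — lesion-free bifurcation, triphasic waveforms (CFA PSV
  0.9 m/s, reverse fraction 0.3; SFA 0.7; DFA 0.85), the patent-limb
  regime;
* occlusion-prone — endograft in the proximal SFA with its proximal edge
  1.2 cm from the junction (< 3 cm, as in the clinical setting), a tight
  65%-severity edge stenosis immediately upstream, a 50% widened
  graft-entry segment distal to it (the stasis pouch — the analogue of
  the contrast-devoid proximal graft regions seen at thrombolysis), and
  severely damped monophasic inflow (CFA PSV 0.38 m/s, SFA 0.20 m/s,
  collateral-dominant triphasic DFA 0.85 m/s) consistent with combined
  inflow disease and a failing graft.

With these conditions the pipeline reproduces the qualitative clinical
contrast: the control's TAWSS stays above 0.4 Pa everywhere, while the
occlusion-prone case shows large proximal-SFA wall fractions below
0.4 and 0.15 Pa, a minimum near 0.045 Pa located at the graft's proximal
edge, and a virtual angioplasty of the edge stenosis that roughly doubles
that minimum (crossing 0.05 Pa upward). Geometric severities and PSVs
were chosen, within clinically plausible ranges, so that the analogue
exhibits the documented deep-stasis regime; they are fixed study
conditions, not fitted quantities, and absolute TAWSS values from the 2D
analogue are not comparable to 3D patient values.

The coarse profile used by tests and examples runs each case in ~2–4
minutes on one core: 0.5 mm base resolution (0.25 mm in lesion/jet
zones, giving meshes of 2–4 k nodes), CFL-limited Δt ≈ 5×10⁻⁵ s, 3
cardiac cycles to periodicity. A production profile would increase
resolution and tighten the periodicity tolerance; convergence behavior
under refinement is characterized by the channel oracles.

## Known limitations

* 2D planar analogue: no helical/secondary flow, no out-of-plane lesion
  geometry; daughter-branch shear scales are compressed by the single
  depth conversion.
* Newtonian viscosity and rigid walls (see above).
* The TAWSS floor of a coarse run is noise-limited: wiggles in the
  explicitly convected Galerkin solution rectify into the |τ| average at
  the few-hundredths-of-a-Pascal level in strongly separated regions.
* The cycle-to-cycle variability of separated flow bounds the achievable
  periodicity tolerance on coarse meshes.
* Oscillatory accuracy at physiological amplitude is limited by the open
  outlet during reverse flow (backflow penalization stabilizes but does
  not make the boundary data exact).
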