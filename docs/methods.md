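# Methods

## Registration model

The template volume `T` (end-diastole) defines the reference
configuration of a hexahedral LV model; the target `S` (end-systole) is
fixed.  The deformation map φ(X) = X + u(X) is found by driving the model
to quasi-static equilibrium under two loads:

1. **Image forces.**  The image energy U = ψ/2 (T(X) − S(φ(X)))² is
   integrated over the mesh by 2×2×2 Gauss quadrature, with `T` sampled at
   reference Gauss positions and `S` at the deformed ones.  Its negative
   displacement gradient, ψ (T − S(φ)) ∂S/∂φ weighted by shape functions,
   is applied as a configuration-dependent nodal force, re-evaluated at
   every Newton iteration.  Both images are interpolated trilinearly and
   the gradient is the analytic in-cell gradient of the interpolant, so
   the assembled force is exactly the negative energy gradient (verified
   by finite differences in the tests).  Outside the grid, intensity and
   gradient are zero: background in gated cardiac PET is near-zero counts,
   and forces should vanish where there is no data.

2. **Active contraction.**  A time-varying-elastance fiber stress
   T⁽ᵃ⁾(a⊗a) is added to the passive Cauchy stress, with

       T⁽ᵃ⁾ = Tmax · Ca₀²/(Ca₀² + ECa₅₀²) · activation,
       ECa₅₀ = (Ca₀)max/√(exp[B(l − l₀)] − 1),

   l = λ·l_r the sarcomere length, and tension ≡ 0 for l ≤ l₀ (both sides
   of the law go to zero continuously at l₀).  Constants: (Ca₀)max =
   4.35 µM, B = 4.75 µm⁻¹, l₀ = 1.58 µm, l_r = 2.04 µm, Ca₀ = (Ca₀)max,
   Tmax = 135.7 kPa (peak isometric tension, configurable).  The
   activation is *subject-specific*: activation = ψₐ·Ct clamped at zero,
   where Ct is the signed mismatch (T − S(φ)) averaged per element and
   then over all elements.  Since both terms of Ct are functions of the
   current configuration, Ct is re-evaluated as the solve progresses:
   contraction is self-limiting — it proceeds until the model overlies the
   target wall and the mean mismatch stops driving it.  The uniform
   activation produces a transmurally uniform contractile stress; the
   local image forces supply the spatial detail.

The analysis runs over pseudo-time t ∈ [0, 1] in 30 equal steps: ψ = t·ψ_max
over the whole course; ψₐ ramps linearly to ψₐ_max at the knot t = 2/3 and
is then held constant.  The pseudo-time is a loading schedule, not
physical time.

## Passive constitutive model

A standard transversely isotropic, nearly incompressible form:

  W = μ/2 (Ī₁ − 3) + c₁(exp[c₂(λ − 1)²] − 1)·[λ > 1] + κ/2 (ln J)²

with Ī₁ = J^{−2/3} tr C, C = FᵀF, λ = √(a₀·C a₀).  Defaults μ = 2 kPa,
c₁ = 0.35 kPa, c₂ = 9, κ = 100 kPa.  The fiber reinforcement acts only in
tension (no nonphysical compressive buckling stiffness); incompressibility
is enforced by penalty, adequate at this scale (registered fields show
J within a few percent of 1).  Stress is derived exactly from W
(second Piola–Kirchhoff, pushed forward); the tests check ∂W/∂F against
finite differences and objectivity under random rotations to 1e-10.

## Solver

Total-Lagrangian Newton iteration.  The element tangent is obtained by
complex-step differentiation of the (complex-analytic) element internal
force — exact to machine precision, which gives quadratic convergence; the
pure-mechanics solver converges to a relative residual of 1e-8.  The
registration driver augments the tangent with (a) the Gauss–Newton part of
the image-force stiffness, ψ ∇S∇Sᵀ NₐN_b (symmetric positive
semidefinite), and (b) the exact rank-one activation-feedback coupling
(∂f_int/∂activation)(∂activation/∂u), applied by a Sherman–Morrison
update.  Without (b), strong activation levels are unconditionally
unstable because the self-limiting feedback is invisible to the tangent.
Safeguards: backtracking line search on the residual norm, a 2 mm cap on
the Newton step (the image force field is only piecewise smooth), and
bisection substepping of a failed pseudo-time increment down to 1/8 of
its nominal size.  Registration steps converge to 2% of the applied
image-load norm: the trilinear force field's cell-face kinks put a floor
of order 1% of the load on the achievable residual, and tightening beyond
it only costs iterations.

Boundary conditions: basal-plane nodes are fixed longitudinally, and the
tangential component is fixed for the basal nodes on the four cardinal
directions, removing in-plane rigid translation and rotation while
leaving radial basal motion free.

## Mesh, fibers, frames

The LV wall is the region between concentric prolate ellipsoids
(epicardial semi-axes 31/48 mm, wall thickness 9 mm), truncated by a
planar base at z = +16 mm and an open apex at z = −30 mm, meshed as a
structured 24×8×4 (circumferential × longitudinal × transmural) hexahedral
lattice (768 elements, 1080 nodes).  The apical cap is excluded: 2D
short-axis strain sampling is not defined on the cap, and near-cap
elements degrade in quality.  Wall depth runs 0 (epi) to 1 (endo).  Fiber
inclination is piecewise linear in depth through (−82°, 0°, 80°); the
fiber is the circumferential frame vector rotated about the outward wall
normal, i.e. it stays in the wall-tangent plane.  The ±5% perturbation
rule scales the triple and rounds to whole degrees: (−86, 0, 84) and
(−78, 0, 76).  Local frames: radial = outward normal of the constant-depth
surface, longitudinal = apex-to-base tangent, circumferential closes the
triad; on the open-apex mesh the normal tilts smoothly and no degenerate
apex branch is needed.

## Phantom (synthetic study conditions)

The phantom emulates a gated cardiac PET pair at desk scale: 64×64×16
voxels at 3×3×7 mm (the clinical grid, 100×100×42 at 1.5×1.5×3.5 mm, is
one flag away and is used for the noise-statistics checks).  Rendering is
a binary wall indicator (wall 100, background 5, arbitrary units)
convolved with an isotropic Gaussian of 4 mm FWHM — a high-resolution PET
scanner's point spread.  The deformation is closed-form and exactly
inverted for rendering the target:

* in-plane radial contraction r → √(r² − c(z)) with c(z) set so the
  endocardial circumference shortens by s(z), graded linearly from 0.22 at
  the base to 0.36 at the apex tip (normal systole contracts more
  apically; the gradient also gives the truth table slice-wise variance,
  without which R² against truth would be dominated by binning noise).
  The map preserves in-plane area, so the wall thickens exactly as an
  incompressible wall must (det F = 1 in the wall; endocardial radial
  strains reach ≈ +0.5);
* torsion linear in z, zero at the base, 8° base-to-apex;
* the target frame is dimmed by 8% — gated PET pairs show a systolic
  intensity drop of this order between frames.  This matters beyond
  realism: with exactly equal brightness the mismatch average crosses zero
  before alignment is complete and the active term switches off early,
  which makes contraction-ablation studies degenerate.

What the phantom does **not** emulate: PET reconstruction noise
(the additive Gaussian degradation model is itself an idealization),
longitudinal base-to-apex shortening and through-plane motion, regional
heterogeneity (it is axisymmetric, so region labels carry no strain
contrast), papillary muscles, and the right ventricle.  Passing tests
therefore demonstrate correct mechanics and registration behaviour under
controlled conditions, not clinical performance.

## Penalty calibration

ψ_max and ψₐ_max are not universal constants; they were calibrated once on
the reference phantom — the smallest order-of-magnitude ψ achieving at
least 80% mismatch-energy reduction, then the minimum ψₐ that measurably
improves alignment over the image forces alone — and frozen: ψ_max = 1e-3,
ψₐ_max = 3e-3 (per intensity-mismatch unit).  Larger ψₐ over-contracts:
the 8% brightness offset keeps Ct positive near alignment, so activation
persists at the end of the analysis and the equilibrium between active
tension and image forces over-thickens the wall.  The ramp ordering (ψₐ
plateaus at 2/3, ψ keeps growing) means contraction does the early global
alignment and image forces dominate the endgame.

## Strain comparison

Strains are sampled like a 2D HARP tagged-MRI analysis: per short-axis
slice (one per longitudinal element band), the projected strain is
averaged over Gauss points in each of 4 anatomical regions (anterior +y,
lateral +x, posterior −y, septal −x) × 3 transmural bands (depth
[0, ⅓) epicardial, [⅓, ⅔) midwall, [⅔, 1] endocardial) — 12
circumferential + 12 radial values per slice.  Statistics: R² (squared
Pearson), %RMSE = √(mean per-entry (ε_ref − ε_pred)²/ε_ref²) with
reference entries below 0.01 excluded and counted (near-zero denominators
make the per-entry form unstable; a ratio-of-sums variant is available),
Bland–Altman bias and 1.96·SD limits with a least-squares trend slope of
differences on means, and a two-sided paired t-test (p = 1 for exact
agreement; a 0 sentinel for a constant nonzero shift).

## Numerical details and degenerate inputs

* Quadrature is 2×2×2 Gauss everywhere; mesh Jacobians are validated
  positive at build time, and element inversion during solving raises with
  the element id.
* Trilinear sampling reproduces voxel-center values exactly; a half-voxel
  linear fade surrounds the outermost voxel centers before the
  outside-is-zero region.
* add_noise requires a non-constant image (σ_i = 0 has no defined SNR);
  SNR ≥ 1e12 is treated as exactly noise-free.  Template and target are
  degraded with independent seeds.
* Identical template and target is an exact fixed point: zero mismatch,
  zero Ct, zero forces, zero displacement.
* Comparison of identical tables reports R² = 1 when variance exists and
  NaN (never an exception) when it does not.

## Problem sizes

Defaults were chosen so a full registration (30 steps, 768 elements,
desk-scale images) takes about a minute on one CPU, and the complete
validation-plus-ablation pair a few minutes.  Halving the image grid
changes the analytic truth not at all and recovered strains only mildly;
the clinical-resolution grid changes image sampling density but not the
mesh problem size.

## Known limitations

* The activation is spatially uniform; perfusion-defect-aware contraction
  (masking elements from the active stress) is out of scope.
* Single target frame: no multi-frame sequential registration.
* The Gaussian degradation model does not represent reconstructed-PET
  noise statistics.
* Radial strains are systematically underestimated at the endocardium
  where the true transmural gradient is steepest — visible in the
  Bland–Altman trend slope — a resolution effect of the 4-layer
  transmural discretization.
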