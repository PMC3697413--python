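# warpstrain

Finite-element **hyperelastic warping** for measuring left-ventricular
systolic strain from gated cardiac image volumes (PET-like data), with a
synthetic LV phantom for validation and the statistics used to compare
two strain methods.

## The problem

Gated nuclear imaging shows *where* the myocardium is at end-diastole and
end-systole, but wall motion and thickening are only indirect measures of
function.  Regional **strain** is the direct one.  `warpstrain` estimates
it by deformable image registration: a hexahedral finite-element model of
the LV wall, built on the end-diastolic (template, `T`) volume, is
deformed onto the end-systolic (target, `S`) volume.  Because the model
carries a realistic myocardial constitutive law, the recovered deformation
map φ(X) = X + u(X) yields full 3D Green–Lagrange strains
E = ½(FᵀF − I), F = ∂φ/∂X, projected onto circumferential and radial
cardiac directions.

## The method

The registration minimizes a total energy

  E(φ) = ∫ W(X, C) dv − ∫ ψ/2 (T(X) − S(φ(X)))² dv,

whose image term generates body forces ψ (T − S(φ)) ∂S/∂φ — force
magnitude from the intensity mismatch, direction from the target gradient.
`W` is a nearly incompressible transversely isotropic strain energy
(neo-Hookean matrix, exponential tension-only fiber reinforcement along a
transmural helix of inclination angles −82°/0°/80°, bulk penalty).

On top of the passive stress acts a **subject-specific active
contraction** (time-varying elastance): the fiber tension

  T⁽ᵃ⁾ = Tmax · Ca₀² / (Ca₀² + ECa₅₀(l)²) · ψₐ·Ct,
  ECa₅₀(l) = (Ca₀)max / √(exp[B(l − l₀)] − 1),  l = λ·l_r,

vanishes below the zero-tension sarcomere length l₀ = 1.58 µm and is
driven by Ct, the template–target intensity mismatch averaged over all
mesh elements — so the model contracts exactly as much as the residual
misregistration demands.  The analysis runs in pseudo-time t ∈ [0, 1]:
ψ ramps linearly throughout, ψₐ ramps to its plateau at t = 2/3.  Each
step solves quasi-static equilibrium by Newton iteration with an exact
complex-step element tangent.

A `phantom` module synthesizes the study conditions: a truncated-ellipsoid
LV with analytic systole (graded circumferential shortening, incompressible
transmural thickening, torsion) rendered into blurred PET-like volumes,
with exact ground-truth strains.  `strain_compare` implements the
evaluation: a HARP-style sampling layout (4 regions × 3 wall depths ×
short-axis slice, i.e. 12 circumferential + 12 radial samples per slice),
R², %RMSE = √(mean[(ε_ref − ε_pred)²/ε_ref²]), Bland–Altman limits of
agreement with a trend regression, and paired t-tests.

## Worked example

`python examples/02_register_phantom.py` registers the default desk-scale
phantom pair (64×64×16 voxels at 3×3×7 mm, 768-element mesh; about two
minutes on one CPU) and prints:

```
mismatch energy: 5.29e+07 -> 3.06e+06 (ratio 0.058)
activation trace: peak 0.006, final 0.004
circumferential  R^2 = 0.900  %RMSE = 0.130  bias = +0.0190  p = 0.000
radial           R^2 = 0.901  %RMSE = 0.412  bias = -0.1187  p = 0.000
```

The registration removes 94% of the intensity-mismatch energy and the
recovered strains track the analytic truth with R² = 0.90 in both
directions.  The Bland–Altman bias shows the characteristic strain
underestimation of the method — small circumferentially, larger (and
magnitude-dependent) radially, where true transmural gradients are
steepest.  `examples/04_sensitivity_harness.py` repeats the analysis with
image noise, reduced intensity, ±5% fiber-angle perturbations
(−82/0/80 → −86/0/84 and −78/0/76), and the active contraction ablated —
ablation leaves visibly worse alignment and lower R², the signature that
the contraction term does the global work that local image forces cannot.

A thin CLI mirrors the library: `warpstrain phantom`, `warpstrain degrade
--snr 4`, `warpstrain register --template a.nii.gz --target b.nii.gz --out
run/`, `warpstrain compare ref.csv pred.csv`.

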