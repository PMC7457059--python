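# Methods

## Scope and intent

`sijstrain` re-creates, at desk scale, a patient-specific CT-to-FEA pipeline
for canine sacroiliac-joint (SIJ) ligament strain. The original pipeline's
inputs (patient CT volumes) are confidential, so the package substitutes a
**parametric landmark model** of a 25 kg Labrador pelvis and treats everything
downstream — constitutive laws, spring topology, load battery, strain
averaging, repeatability regression, lesion-count statistics — as first-class,
tested code. Results therefore characterize the *method* (its determinism,
symmetry, calibration and statistical behaviour), not any real dog.

## Geometry

Coordinates are mm, right-handed: origin at the mid-sagittal point between the
acetabula, +x lateral to the right, +y dorsal, +z cranial. The canonical
landmark set is exactly mirror-symmetric about x = 0 and contains, per side:
1 acetabular support point, 4 + 4 dorsal and 4 + 4 ventral sheet-ligament
attachment points (sacrum/ilium), 10 + 10 SIJ points, the sacrotuberous
origins on S3 and C1 and its tuberosity insertion; plus midline load point and
sacrocaudal interface points. All coordinates are **synthetic defaults** sized
loosely to a 25 kg Labrador (inter-acetabular span 70 mm, sacrum ~60 mm long,
tuberosities 45 mm caudal); none are measured values. Linear dimensions scale
as `scale * (body_mass / 25 kg)^(1/3)` (isometry), the joint area with its
square.

## Constitutive laws

Units are N, mm, MPa internally (1 MPa·mm² = 1 N); bone moduli quoted in Pa
are converted on entry.

- **Bone** (kept for the derived-moduli contract; the mechanics treats bone as
  rigid): isotropic, E = 1.7e10 Pa, ν = 0.3, K = E/(3(1−2ν)), G = E/(2(1+ν)).
- **Ligaments**: stiffness is a step function of tensile strain — 39, 55, 103,
  100 N/mm on [0, 2.5%), [2.5, 5%), [5, 10%), [10%, ∞) — and identically zero
  for ε ≤ 0. Bands are half-open, closed on the left, so ε = 0.10 maps to
  100 N/mm; the published band table is ambiguous exactly at its breakpoints
  and this choice makes the lookup total and deterministic. The 103 → 100
  non-monotonicity is kept as printed. Stiffness is read as force per unit
  **elongation** indexed by strain; force is its integral over elongation
  (continuous, piecewise linear) and energy the second integral (C¹), which is
  what the energy-minimizing solver needs.
- **Sacrocaudal joint**: compressive tangent modulus E(ε) = 20.71 ε + 234 ε²
  MPa with ε the compressive strain *magnitude*, zero in tension. As printed
  with a signed ε < 0 domain, the polynomial would give a negative modulus at
  small compression, contradicting the stated "increasing stiffness when
  compressed"; the magnitude convention preserves the printed coefficients and
  restores monotonicity. Stress is the exact antiderivative,
  σ(ε) = 10.355 ε² + 78 ε³ MPa, and the element force is σ·A with
  ε = (t₀ − gap)/t₀ over interface area A (default 200 mm², a synthetic
  config value) and reference gap t₀.
- **Mooney–Rivlin surrogate**: the 3-parameter incompressible solid
  W = c₁₀(I₁−3) + c₀₁(I₂−3) + c₁₁(I₁−3)(I₂−3) is fitted to the joint stress
  curve sampled at 60 uniform points on compressive strain [0.01, 0.30]. The
  compressive strain is interpreted as **logarithmic** strain (stretch
  λ = e^(−ε)) paired with **true (Cauchy) stress** λ·∂W/∂λ — the standard
  large-deformation pairing. This choice matters: with engineering strain
  (λ = 1 − ε) and nominal stress, no 3-parameter fit can get closer than ~6%
  max relative error to this curve, whereas the log-strain/true-stress pairing
  achieves 1.3%. Because the model is linear in (c₁₀, c₀₁, c₁₁) the fit is a
  relative-error-weighted linear least-squares problem — deterministic, no
  iteration — and the worst residual over the sample is recorded on the
  fitted object. The nominal-stress function is exposed separately for users
  who want the conventional uniaxial form.

## Mechanics

Bones are rigid: ligament stiffness (~10² N/mm) is many orders of magnitude
below bone stiffness, so ligament strain is dominated by rigid-body motion of
the sacrum and C1. A rigid hemipelvis fixed at its acetabulum is fixed
everywhere, so the ilium/ischium attachment points are fixed environment. The
configuration space is 12-dimensional: translation plus rotation vector for
each free body.

The SIJ springs, like all ligaments, carry no compression; in a continuum
model bone-on-bone contact would. A compression-only linear penalty (default
10³ N/mm, configurable, off with 0) across each SIJ spring pair stands in for
that contact and prevents interpenetration — a disclosed deviation from a pure
spring network. A grounding spring (10⁻⁶ N/mm on translation, with a 50 mm
rotational arm) keeps the pose determinate when every tension-only element is
slack; the solver warns if its energy exceeds 10⁻⁶ of the elastic energy at
convergence.

Loads are dead (direction-fixed) forces at the sacral load point. Equilibrium
minimizes total potential energy — spring + joint + penalty + grounding energy
minus load work — which is C¹ but only piecewise C²: forces are continuous
across stiffness-band crossings while the tangent stiffness jumps. L-BFGS-B
with analytic gradients (the rotation part uses the SO(3) right Jacobian) gets
near the minimum; a damped Newton polish on the gradient with a
finite-difference Hessian then drives the gradient norm to ~10⁻¹⁰, giving
independent force/moment balance residuals below 10⁻⁶ N (N·mm) on every
battery scenario. Guards raise a mechanism error if rotation exceeds 0.5 rad
or translation 100 mm. Everything is deterministic: repeated solves are
bitwise identical.

The battery is the fixed eight-row table (0, ±200), (±200, 0), (±141.4,
±141.4) N in (x, y); 141.4 is stored exactly as printed (200·cos45° rounded to
one decimal), keeping the table bit-stable. Per-spring strains are averaged
arithmetically per ligament group and side; the SIJ springs are computed and
exported but excluded from the named-ligament grid (they are not one of the
reported ligament groups), giving 8 × 3 × 2 = 48 cells; `include_sij=True`
widens the grid to 64 cells.

## Repeatability study

Operator variability in re-placing attachment points is emulated by i.i.d.
zero-mean isotropic Gaussian perturbation of every spring attachment class
(supports, load point and joint interfaces stay fixed), one seed per trial.
The default sd of 0.25 mm is a package choice — sub-voxel relative to the
0.625 mm slice spacing the geometry presumes, i.e. careful manual placement;
no published value exists for it. Each trial rebuilds the model from the
perturbed geometry (rest lengths re-derived, so each trial's reference is
stress-free) and runs the full battery.

Each of the 48 cell series over 5 trials is regressed on trial index with
closed-form OLS (slope = Sxy/Sxx, t-based two-sided p and symmetric 95% CI on
n − 2 df). No multiple-comparison adjustment is applied, matching the
exploratory design. Degenerate cases a deterministic pipeline can produce:
zero-variance series are repeatable by convention (slope exactly 0, t
undefined); an exact nonzero-slope line (zero residual) is treated as p = 0.
Both are flagged. With sd = 0 the study is perfectly repeatable (48/48, all
slopes identically zero); with noise and no drift, rejections are type-I
events at rate ≈ α. The original study's specific 47/48 outcome and its
slope/CI tables depend on unreleased per-trial data and are not reproduction
targets.

## CT phantom

The segmentation stage is exercised by a synthetic volume: four ellipsoidal
bone solids (sacrum, two hemipelves, C1) at a bone-like intensity over zero
background, 226 transverse slices at 0.625 mm by default, plus one voxel per
landmark carrying a unique fiducial intensity. `threshold_segment` thresholds,
labels connected components, and maps components to bone names via the
generating solids' centres, raising a named ambiguity error when a
too-low threshold merges bones. Fiducial recovery reads the coded voxels back
from the image and returns landmark positions to within half a voxel. This
replaces manual tracing — deliberately, since manual tracing is exactly the
operator-variability source the noise model emulates. Volumes export to NIfTI
and iso-surfaces to binary STL.

## Lesion-count statistics

The cohort generator draws independent Poisson counts per dog, lesion type and
side; defaults are a 6/10/6 Breeder/Detection/Other cohort with per-side means
set to half the published group-average totals, and a covariate mix (sex, age
band) loosely matching the described sample. Negative-binomial overdispersion
is available by configuration. The analysis battery per lesion type × side
(L, R, total → 21 omnibus tests):

- one-way ANOVA (textbook between/within decomposition; an all-constant
  response yields F = 0, p = 1);
- Fisher's protected LSD: pooled-MSE pairwise t-tests on the within df,
  evaluated **only** when the omnibus p clears the protection threshold
  (default 0.10, reflecting the exploratory "p < 0.10 is evidence" rule;
  pairwise significance at 0.05). Two-sided p-values throughout — the halved
  "p/2" notation sometimes seen for one-sided contrasts is not emulated;
- factorial ANOVA with work status, sex, age and the work-status interactions,
  Type III sums of squares via full-vs-reduced fits with sum-to-zero coding
  (matching the common GLM default; Type II is a straightforward variant).
  Single-level factors are reported inestimable; aliased effects are flagged
  with zero df rather than raising.

The published cohort's specific p-values depend on per-dog data that were
never released; the tests instead verify the machinery against independent
oracles (scipy, statsmodels) and calibrate its type-I rate by simulation.

## Problem sizes and tolerances

Default problem sizes are chosen so the full pipeline is interactive: one
battery (8 equilibrium solves over 12 DOF) takes ~2 s, the five-trial study
~6 s, and the phantom ~2 s at 1 × 1 × 0.625 mm. Key numeric defaults:
equilibrium gradient tolerance 10⁻⁶ N (polished ~10⁻¹⁰), FD gradient checks at
10⁻⁵ relative, OLS/ANOVA oracle agreement at 10⁻¹⁰–10⁻¹², Monte-Carlo
calibrations at 1000–2000 replicates with ±0.02 tolerance on a nominal 0.05
rate.

## Limitations

- Geometry is synthetic; strain magnitudes are illustrative, not predictive
  for any dog. No muscles, no pubic symphysis, no articular contact surfaces.
- Rigid bones: bone compliance would perturb ligament strains slightly; the
  original deformable-bone field quantities (deformation and equivalent
  stress maps) are out of scope.
- Tissue parameters are human-derived literature values; no canine validation
  exists for them.
- The operator-noise model is isotropic and i.i.d.; real placement error is
  likely anisotropic and spatially correlated, so the simulated repeatable
  fraction calibrates the statistics, not the human.
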