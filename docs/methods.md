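# Methods

## Physical model and assumptions

The package solves the electro-quasi-static boundary-value problem

    div( sigma*(x, f) grad phi ) = 0,    sigma* = sigma(f) + j 2*pi*f eps0 eps_r(f),

on a labeled voxel volume. The approximation neglects wave propagation and
magnetic induction, which is appropriate for conduction-dominated contact
currents below ~1 MHz. Air is excluded from the computational domain
entirely: capacitive displacement through air is negligible in this band, so
the body–air surface carries a homogeneous Neumann condition. Electrodes are
voltage-driven: all source-contact voxels are fixed at the touch voltage U_t
(multi-electrode sources such as "both hands" are equipotential) and sink
voxels at 0 V. eps0 is fixed at 8.854e-12 F/m; DC is encoded as f = 0, which
takes a real-arithmetic fast path through the same code.

Solutions are complex phasors. Linearity in U_t is exact, which is why the
heart-current factors are touch-voltage invariant; the suite asserts this to
~1e-13 and the contract is 1e-9.

## Discretization and solver

Finite volume on the uniform voxel grid, 7-point stencil. Face admittances
use the harmonic mean of the two adjacent voxel sigma* values times the
geometric factor (face area / center distance); the harmonic mean keeps the
normal current continuous across material interfaces and does not
overestimate current through thin resistive layers such as the contact-skin
slice (an arithmetic mean would). Faces to air carry zero flux. Dirichlet
rows are eliminated before solving.

Solver strategy: sparse LU (SuperLU) for systems up to 20k unknowns and on
request; above that, Jacobi-preconditioned CG for the real SPD DC systems and
Jacobi-preconditioned BiCGSTAB for the complex-symmetric AC systems. The
default relative-residual tolerance is 1e-8 (internal Krylov tolerance is two
orders tighter); non-convergence raises with iteration diagnostics. There is
no randomness anywhere in the solve path, so identical inputs give identical
outputs bit-for-bit.

E = -grad(phi) uses central differences at interior voxels and one-sided
differences where an axis neighbour is air; J = sigma* E per voxel. The body
current is measured as the flux of the *face* currents (the same harmonic-mean
conductances the matrix uses) through full grid planes between the source and
sink electrodes, so charge conservation makes the plane-to-plane spread a
pure solver-error diagnostic: it sits at 1e-8 or below on converged solves,
against a 1% contract.

Analytic anchors: homogeneous bars and layered slabs between full end-face
electrodes are reproduced to machine precision (the discrete solution is
exact for piecewise-linear potentials); a staircase-rasterized cylinder
converges monotonically to L/(sigma A) under grid refinement (23% error at
4 mm, 1.8% at 2 mm, 0.6% at 1 mm for a 10 mm radius).

## Contact models

Z_Total = Z_Skin + Z_Intern. Two body-model variants realise this:

* **Intern-BM** — the skin under the 100 x 100 mm contact patch is relabeled
  to the tissue beneath it and the drive potential is imposed directly on the
  exposed subcutaneous voxels.
* **Total-BM** — additionally, a 2-mm slice of the contact electrode adjacent
  to the body carries the touch-voltage-dependent skin properties, and the
  remaining electrode bulk is a 1.0 S/m conductor (orders of magnitude above
  the 0.2 mS/m ELF skin conductivity, so the bulk contributes nothing to the
  assessed quantities, while staying within a solver-friendly dynamic range).
  When the voxel pitch cannot realise 2 mm exactly, the slice is built one
  voxel thick and its sigma and eps_r are scaled by (voxel thickness / 2 mm),
  which preserves the slab impedance of the slice exactly.

The slice properties are tabulated at 25/50/100/220 V
(sigma = 0.14/0.19/0.27/0.85 mS/m, eps_r = 2.4/3.9/6.4/13.2 x 1e4) and
log-log interpolated between voltages; extrapolation outside [25, 220] V is
refused because no data exists there. The conductivity rises by a factor of
~6 (0.85/0.14) between 25 and 220 V.

Regime selection (intact skin, U_t <= 220 V): Total-BM up to 1 kHz,
case-by-case between 1 and 10 kHz, Intern-BM above 10 kHz; above 220 V the
skin breaks down and Intern-BM applies everywhere. Interval boundaries are
closed below / open above (1 kHz -> Total, 10 kHz -> case-by-case, 220 V ->
intact-skin row); the table's printed interval labels overlap, so a
convention had to be fixed and this one is it. Voltages below 25 V are
classified with a warning (outside the validated range). Case-by-case
scenarios are never decided silently: campaigns skip them with a logged
warning unless a mode is forced.

`fit_skin_properties` recovers (sigma, eps_r) per voltage from reference
|Z_Total|(f) curves by least squares on the relative magnitude error over
points up to 1 kHz, in log-parameters. Only the magnitude is fitted (the
available reference sources report |Z|, not phase). Because the anchor
frequency of tabulated permittivities is generally unknown, the fit reports
its signed residual-vs-frequency profile rather than assuming one. Noiseless
synthetic curves are recovered to machine precision; under the reference
noise model (5% multiplicative, 8 points) a 200-seed Monte-Carlo puts the
worst-case recovery error near 30% and the median near 9%, and the tests
assert those established bounds.

## Dose quantities

* **E99Heart**: per-voxel phasor amplitude |E| = sqrt(|Ex|^2+|Ey|^2+|Ez|^2)
  over the ventricular-myocardium label only (lumen blood, vessels and
  everything else excluded), reduced to the 99th percentile with linear
  interpolation between the two bracketing order statistics. Compliance
  guidelines do not fix the interpolation rule, so it is stated here and
  pinned by a brute-force sorting oracle in the tests.
* **E_Sam**: for each of three orthogonal trans-cardiac segments,
  V_i = integral of E . dl (trilinear field interpolation, 1-mm steps,
  trapezoid rule), E_i = |V_i| / L_i. The three orthogonal estimates are
  combined as the Euclidean norm sqrt(E1^2+E2^2+E3^2) — the unique
  rotation-consistent combination for a homogeneous unidirectional field,
  which is exactly the assumption the probe method makes. A segment leaving
  the body is an error.
* **Heart current factors**: F(p, f) = [E(p,f)/|I(p,f)|] / [E(ref,f)/|I(ref,f)|]
  with ref = LH-BF, computed as a ratio of per-path ratios so the reference
  row is 1.0 exactly in floating point. |I_Body| enters as a magnitude; the
  current phase is reported separately in the dose tables.

Cross-section planes for I_Body default to four planes at even fractions of
the gap between the electrode extents along the dominant source-to-sink axis;
plane positions are overridable per call, and a plane that misses the body is
an error.

## The synthetic phantom

Geometry (all dimensions configurable, mm): trunk as an elliptic cylinder
with concentric skin (4) and subcutaneous fat (8) layers; legs and T-pose
arms as cylinders; spine and long bones; two lung ellipsoids flanking an
ellipsoidal heart (myocardium shell around a blood lumen, wall 14–16 mm at
default scale); and 20-mm-diameter blood vessel channels: left/right
subclavian analogues running from inside each arm to the lumen, and an
aorta/vena-cava analogue from the lumen to the lower trunk. Electrode
patches are registered at the seven standard sites as first-surface voxel
sets inside 100 x 100 mm windows; actual patch areas land between 80 and
104 cm^2 depending on surface curvature.

Two further features exist because the channeling mechanism needs them, and
both have anatomical counterparts:

* a **pericardial fat sheath** (8 mm) around the heart, open below an
  aperture plane at 70% of the inferior semi-axis — the apex region where
  the heart rests on the diaphragm. It decouples the myocardium from the
  ambient trunk gradient so that what reaches the ventricle wall is
  predominantly what the vessels deliver;
* **perivascular/mediastinal fat** (8 mm) sleeving the vessel course (with a
  bare distal pickup segment near the hand electrodes). A bare blood tube at
  2:1 conductivity contrast to muscle exchanges current with its
  surroundings over a ~25 mm length scale and therefore merely tracks the
  local tissue potential; the sleeve suppresses that exchange so the
  channels actually transport remote potential toward the heart.

The **no-channeling control** (`vessel_channels=False`) rasterizes the same
vessel tubes but fills them with muscle, leaving every other voxel
identical. This is deliberately a "muscle plug" control, not a sealed-shell
control: it isolates the contribution of *blood* conduction while keeping
geometry fixed. Consequently the closed-shell invariant (lumen voxels touch
only myocardium or vessel blood) is enforced for channel-bearing phantoms
and not for the control, whose plugs legitimately pierce the shell.

On the default phantom at 50 Hz, LH-BF: the myocardial E99 is strictly
larger with blood-filled channels than with the muscle-plug control, and
halving the blood conductivity (the post-mortem direction) lowers E99/|I|
by ~6%. One caveat is stated openly: per unit body current the control can
score *higher*, because the vessels also lower the whole-body impedance by
more than they raise the heart field; the channeling comparison is therefore
defined at fixed touch voltage, and sweep factors are normalised against the
baseline campaign's reference path.

What the phantom does *not* emulate: realistic organ shapes, heart valves
(their closure would raise the atria-ventricle impedance and attenuate
channeling), myocardial fiber anisotropy, posture, and any demographic
variability. Passing the qualitative tests shows the pipeline propagates the
modelled mechanisms correctly — not that the absolute factor values transfer
to a real anatomy; on this phantom the transversal factors (e.g. LH-RH
~0.87, RH-BF ~0.75 at 50 Hz) differ from values computed on high-resolution
anatomical models, as expected at this level of geometric abstraction.

## Tissue table

Bundled one-term Cole-Cole parameters for muscle (isotropic at the
longitudinal, along-fibre conductivity — the anisotropic and longitudinal
setups are known to agree closely for these scenarios), fat, cortical bone,
inflated lung, blood, ventricular myocardium, intact dry skin (0.2 mS/m at
ELF), plus the constant 1.0 S/m electrode bulk. They are representative
literature-style values, not a database replication; every entry can be
overridden from a user YAML table, and per-tissue conductivity scaling
supports the blood sweep. The loader validates positivity, eps_r >= 1, and
the Cole-Cole term constraints; the bundled set satisfies
sigma non-decreasing / eps_r non-increasing over [0, 1 MHz] by construction
of the relaxation form.

## Problem sizes and runtimes

Two standard configurations: the default phantom (~1 m reduced-stature
adult-proportioned body, 4 mm voxels, ~366k body voxels; one AC solve
~25 s on one core) used for the factor campaign and the anatomy-effect
checks, and a tiny preset (~0.45 m, ~44k voxels, ~1 s per solve) used for
structural, impedance-regime, linearity and reciprocity checks. In the tiny
body the vessel occupies most of the slender arm core, which exaggerates the
vessels' share of the limb impedance; directional blood-conductivity claims
are therefore asserted on the default phantom only. Reciprocity and
voltage-invariance checks run at DC with the direct solver (or CG at 1e-12)
where agreement reaches ~1e-13.

## Degenerate inputs and error policy

Negative frequencies, non-positive touch voltages, zero electrode sets,
overlapping source/sink sites, spacing outside [1, 5] mm, sub-voxel tissue
layers, configurations that empty a required tissue, electrodes whose patch
window misses the body, Total-BM voltages outside [25, 220] V, heart axes
leaving the body, planes missing the body, and unmapped labels all raise
typed errors naming the offender. Externally loaded label volumes downgrade
connectivity problems to warnings (real segmentations contain floating
voxels). Campaigns record failed solves and continue, reporting failure in
the exit status; completed solves are content-hash cached so reruns are
idempotent and bit-identical.
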