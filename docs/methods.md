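# Methods

`cardiogrowth` characterizes left-ventricular (LV) myocardial growth by an
inverse problem: given a pre-growth LV geometry and a post-growth LV shape
(a binary mask), find the two kinematic growth coefficients whose forward
finite-element simulation best reproduces the observed shape, with DICE
overlap as the similarity objective and Bayesian optimization as the
search strategy.  This note records the models, the numerical choices and
the limits of what the synthetic experiments demonstrate.

## Kinematic growth model

The total deformation gradient decomposes multiplicatively, `F = Fe Fg`.
Only the elastic part stores energy and generates stress; the growth
tensor is a transversely isotropic stretch about the local fiber
direction f:

    Fg = (1 + alpha_f) f (x) f + (1 + alpha_n) (s (x) s + n (x) n)

`alpha_f` models in-series sarcomere addition (longitudinal cell growth)
and `alpha_n` in-parallel addition (transverse growth) in the
sheetlet/sheet-normal plane.  Both live in [0, 1] — a coefficient of 1
doubles the size in its direction — which bounds the inverse search
space.  `det Fg = (1 + alpha_f)(1 + alpha_n)^2` exactly.

The elastic response is the invariant-based Holzapfel–Ogden energy on
`Ce = Fe^T Fe` with swine parameters (a = 1.05 kPa, b = 7.542, a_f =
3.465 kPa, b_f = 14.472, a_s = 0.481 kPa, b_s = 12.548, a_fs = 0.283 kPa,
b_fs = 3.088).  Conventions, each selectable in `MaterialParams`:

* the anisotropic exponentials are `a_i/(2 b_i){exp[b_i (I4i - 1)^2] - 1}`
  so the anisotropic energy is zero in the reference state;
* fiber/sheet terms act in tension only (Macaulay bracket), avoiding
  nonphysical compressive fiber stiffening (`tension_only=False` restores
  the unconditional form);
* near-incompressibility by a volumetric penalty `kappa/2 (ln Je)^2`
  (default kappa = 1000 kPa ~ 1000 a) with an isochoric split of the
  isotropic term.  The `a`-type moduli are taken in kPa, the unit
  consistent with an end-diastolic pressure of 10 mmHg = 1.33 kPa.

The second Piola–Kirchhoff stress is the analytic derivative
`S = 2 d(det Fg psi)/dC`, i.e. the elastic stress pulled back through the
growth tensor; a finite-difference oracle in the test suite pins this
identity at relative tolerance 1e-5.

## Idealized geometry and fibers

Real segmentations are replaced by a truncated prolate spheroid: endo- and
epicardial quadrics with wall thickness interpolated apex-to-base, cut by
a basal plane (`truncation_fraction` of the long axis retained).  The long
axis is +z, base up, lengths in mm.  The apex is closed by a butterfly
(O-grid) block layout — a square patch mapped onto the polar cap through
an elliptical (squircle) grid mapping — so every hexahedron has a strictly
positive Jacobian; collapsed-edge apex elements would also wreck the
explicit solver's stable-increment estimate.  The default study geometry
(endo radii 16/10 mm, wall 3.5–4 mm, 16x3x6 elements plus the cap) is a
desk-scale LV: small enough that a full optimization runs in minutes on
one CPU, proportioned like a mammalian LV (wall/cavity-radius ~ 0.4).
A `from_edge_length` constructor reproduces the CMR-scale regime
(~1.5 mm edges, 4–6 transmural layers on a ~9 mm swine wall) when wanted.

Contour stacks emulating short-axis segmentation can be generated from the
same quadrics, smoothed along the slice direction with cubic smoothing
splines (penalty chosen by generalized cross-validation by default, so
noise-free smooth contours pass through unchanged), and lofted into
open-ended tube meshes.  The closed-apex generator is the path used by the
simulations.

Fibers follow the Laplace–Dirichlet rule-based construction reduced to a
single-chamber wall: a transmural harmonic coordinate (0 endo, 1 epi), an
apicobasal harmonic coordinate (0 apex, 1 base), local directions from
their gradients, and a helix angle interpolated linearly from +60 deg at
the endocardium to -60 deg at the epicardium.  The sign convention (+60 at
endo) and the 0 deg sheet angle are configurable defaults; the source
description fixes only the +/-60 range.  Triads are orthonormal and
right-handed to 1e-9 by construction and by test.

## Boundary conditions and pericardium

End-diastolic pressure (10 mmHg) acts as a follower load on the deformed
endocardial facets.  Longitudinal displacement is fixed on the basal plane
and on the pericardial base ring.  The pericardium is an explicit quad
shell conforming to the epicardium, modeled as a linear elastic membrane
(E = 10 MPa, Poisson 0.3) with frictionless penalty contact against the
epicardial surface.

Three pericardial choices deserve emphasis because the source description
leaves them open:

* **Penalty units.**  The overclosure law "p = 2 h" is stated without
  units.  At growth-level contact pressures (tens of kPa) a slope of
  2 kPa/mm admits several millimetres of interpenetration — the wall
  passes through the shell, and does so mesh-dependently.  The default is
  200 kPa/mm, keeping penetration well below the element size; the slope
  is exposed in the configuration.
* **Shell thickness.**  Never stated; with E = 10 MPa a 1 mm membrane is
  stiff enough that full-range growth (wall volume x 3.2 at alpha_f = 1)
  crushes the apex into element inversion.  The default is 0.25 mm, which
  completes the whole [0,1]^2 protocol except the extreme (1,1) corner
  (that simulation fails only in its final settling phase, after all
  growth checkpoints are emitted; the optimizer records a zero score and
  continues).
* **Membrane stability.**  A bending-free membrane has no compressive
  strength; St. Venant–Kirchhoff compression buckles mesh-dependently.
  The shell is therefore tension-only (tension-field/wrinkling model:
  compressive principal membrane stresses are clamped to zero) and
  heavily damped (20x the body coefficient) — it is physically
  quasi-static, so extra dissipation changes nothing about its settled
  state.

## Explicit quasi-static solver

The damped equations of motion `M u'' = P - I` are integrated with the
central-difference scheme and lumped masses.  Pseudo-time is a loading
coordinate: preload over t in [0,1], growth ramp over t in [1,2], then a
relaxation hold (half a step duration) at constant load and full growth.
Loads and the growth fraction follow smooth-step amplitudes (zero rate at
step ends), the standard quasi-static explicit practice; bare linear
ramps put a velocity discontinuity at the growth onset that alone pushed
the kinetic-energy ratio above 5%.  Intermediate configurations are
emitted when the growth fraction crosses {0.2, 0.4, 0.6, 0.8}; the final
(fraction 1.0) configuration is taken after the hold, i.e. at statics.

Numerical controls, all in `SolverSettings`:

* **Mass scaling.**  The user picks an increment count per step (default
  6000); each element receives the density that makes that increment
  stable (uniform wave-crossing time, safety 0.25, stiffness scale
  kappa + 10(a + a_f + a_s + a_fs)).  Contact adds a nodal mass floor on
  both sides of the interface.
* **Damping.**  Mass-proportional damping at 2.5x the critical estimate of
  the *soft* first structural mode.  The soft-mode frequency is the
  stiff-scale estimate times sqrt(E_soft/E_eff) with E_soft ~ 6a: tuning
  damping to the bulk (kappa-dominated) scale overdamps the physically
  soft response into pseudo-time creep that never converges at practical
  increment counts.
* **Contact.**  Node-to-facet penalty with Newton closest-point projection
  onto the bilinear facet (a centroid-plane gap misreads curvature sag as
  penetration on conforming curved surfaces), rebuilt every 25 increments
  via a KD-tree.  A contact dashpot (2.5x critical, normal and tangential,
  never adhesive) stabilizes the negative tangential stiffness (~ -pA/R)
  that pressurized frictionless contact has on curved surfaces; being
  purely viscous it vanishes in statics, so equilibria remain
  frictionless.
* **Volumetric locking.**  Mean dilatation (element-averaged elastic
  Jacobian in the volumetric term) instead of fully integrated penalties:
  full 2x2x2 integration missed the thick-sphere pressurization oracle by
  ~16–20%; with mean dilatation agreement is ~1% at working resolution.

Quasi-staticity is monitored as the peak kinetic/total-energy ratio after
the initial transient (t >= 0.5); runs with a peak below 5% are accepted.
The solver is deterministic: identical inputs give bitwise-identical
trajectories.  Known limitation: frictionless sliding against the shell
leaves near-neutral tangential modes, so individual epicardial node
positions can differ ~1 mm between increment counts while the occupied
volume (what the DICE objective sees) agrees to <0.1%; the pseudo-time
convergence property is therefore asserted on the shell-free
configuration.

## Shape metrics

Node clouds are rasterized by depositing a separable cubic B-spline kernel
(4-voxel support) at each point; the raw kernel sum is a partition of
unity, saturating near 1 inside densely sampled solids while an isolated
node still peaks at (2/3)^3 ~ 0.30.  The field is thresholded at 0.25 and
closed with a spherical structuring element 6 voxels across.  Because the
working meshes are coarser than the CMR regime the source data assumes,
each hexahedron is re-sampled on a parametric sub-lattice (target spacing
1.5 voxels) before deposition — node-equivalent points, not mesh
refinement.  The default voxel pitch is 0.5 mm, ~1/8 of the wall
thickness, matching the wall-to-voxel ratio of typical short-axis CMR.
Masks read/write NIfTI.

Rigid alignment is ICP (nearest neighbours + Kabsch), PCA-initialized for
arbitrary poses or identity-initialized inside the pipeline, where the
forward model and target share a frame and the near-axisymmetric LV makes
principal axes degenerate.  DICE is `2|A n B|/(|A| + |B|)` on a shared
grid.

## Bayesian optimization

A Gaussian-process surrogate (Matern-5/2 ARD kernel, standardized outputs,
white-noise floor 1e-4 to absorb voxelization discreteness,
marginal-likelihood fitting with fixed random state) interpolates all
observed DICE scores.  The acquisition is the Upper Confidence Bound with
beta = 10 weighting the *variance* — the convention of the usual reference
implementations, so the effective multiplier on the standard deviation is
sqrt(beta) ~ 3.2.  With the multiplier applied to the standard deviation
directly (10 sigma) the loop over-explores and closed-loop recovery error
triples.  The acquisition is maximized on a deterministic 101x101
candidate grid (ties to the lexicographically smallest pair).

Protocol: three corner initializations (0,1), (1,0), (1,1), then ten
iterations of fit-propose-simulate-score.  Every simulation contributes
its intermediate checkpoints as surrogate samples at the scaled
parameters (g alpha_f, g alpha_n) — five evaluations per simulation.  A
diverged proposal scores 0 and the loop continues.  The reported estimate
is the best *observed* sample.  With a fixed seed the whole trace is
reproducible.

## Synthetic validation and its limits

Targets are generated by the forward model at refined settings (element
edge ~2/3, increments x5) and inverted with the standard model, so the
"noise" is forward-model discretization difference and no inverse crime is
committed.  The desk-scale suite runs the two printed growth combinations,
(0.9, 0.3) longitudinal-dominated and (0.1, 0.3) transverse-dominated, on
one geometry; uniform random draws on [0.1, 0.9]^2 (fixed seed) extend it.

What passing these experiments shows: the two-parameter kinematic growth
law is identifiable from shape overlap under discretization-level model
error, with recovery errors of a few percent and optimum DICE above 90%.
What it does not show: robustness to segmentation variability, to material
or boundary-condition misspecification, to spatially heterogeneous growth,
or to growth generated by a different constitutive law — the target
generator shares the model family with the inversion by design.  DICE is
more sensitive to transverse than to longitudinal growth (wall thickening
changes many surface voxels; elongation shifts mostly the apex), so
transverse coefficients are the better-determined direction, and
low-growth targets have larger *normalized* errors purely through the
normalization.

## Problem sizes

Defaults are chosen so every stage is interactive on one CPU: the coarse
inversion model has ~340 hexahedra (simulation ~10 s at 6000 increments
per step), a full 13-simulation optimization takes ~3 minutes, and the
two-case noisy validation suite ~15 minutes.  All sizes scale through the
configuration; the CMR-regime mesh (~40k elements) is supported by the
same code path for forward studies.
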