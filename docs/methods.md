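# Methods

This note documents the models, numerical choices and limitations of
`mptfm`.  Units throughout: lengths in µm, stresses in Pa, forces in
Pa·µm² = pN.

## Coordinate conventions

Colatitude θ ∈ [0, π] from +z, azimuth φ ∈ [0, 2π) from +x, latitude
λ = π/2 − θ.  After cup alignment the phagocytic axis is +z, the cup base
sits at θ = π, and the normalized axial coordinate is
x = (π − θ)/α<sub>rim</sub> with α<sub>rim</sub> the mean angular position
of the contact-mask boundary measured from the base pole.  x may slightly
exceed 1 ahead of the rim (noisy boundary vertices, protruding regions);
values are retained up to 1.05 and clipped for binning.

## Shape reconstruction

Stages: (1) Otsu threshold on a Gaussian-smoothed copy of the particle
channel (σ = 0.3 µm) gives the seed centroid and volume; the largest
connected component wins.  (2) 3000 spherical-Fibonacci rays are cast from
the centroid; intensities are sampled by cubic interpolation at steps of
half the smallest voxel spacing, out to 1.6× the nominal radius.  (3) A
Gaussian is least-squares fitted to the central-difference derivative of
each profile in a ±4-sample window around its most negative sample; the
fitted center is the edge radius.  With noisy data the window is selected
on a lightly smoothed derivative (σ = 1 sample) restricted to 0.6–1.4× the
nominal radius; the fit itself always uses the raw derivative.
(4) Directions whose radius deviates from the median of their 1 µm²
geodesic neighborhood by more than 5 robust deviations (floor 0.2 µm, half
the largest physiological deformation, so genuine indentations are never
discarded) are flagged invalid.  (5) Radii are smoothed by averaging valid
edge radii within a 1 µm² geodesic window on the median-radius sphere;
invalid directions are filled from their neighbors.  (6) The convex hull
of the unit directions provides the triangulation topology, reused for the
true radii (valid for star-shaped targets, which phagocytic deformations
of spheres are).

Derived: S, V, sphericity Ψ = π^⅓(6V)^⅔/S, volume-equivalent radius
R<sub>eq</sub>, median radius R<sub>med</sub>.  Radial deviation maps use
R<sub>med</sub>; the elasticity reference uses R<sub>eq</sub>
(volume-consistent).  Principal curvatures come from a quadric fit (with
linear terms, first-fundamental-form corrected) over the 2-ring
neighborhood in each vertex tangent frame; sign convention H = +1/R for a
sphere.  On a 3000-vertex sphere of radius 3.7 µm the fitted mean
curvature carries a ≈ +0.4 % discretization bias, well inside the ±0.005
µm⁻¹ tolerance used in the tests.

Accuracy (measured on rendered synthetic spheres, voxels 0.2×0.2×0.4 µm):
volume-equivalent radius within 0.4 %, RMS per-vertex radial error ≈ 14 nm
noiseless and ≈ 30 nm at SNR 10.  The residual systematic part comes from
the curvature bias of gradient-based edge localization under anisotropic
blur (≈ σ²/R, largest toward the poles where σ_z = 0.4 µm).

## Surface mapping and cup metrics

Stains are projected by taking, for each vertex, the maximum linearly
interpolated intensity within ±1 µm of the vertex radius along its radial
line.  The contact mask thresholds both channels with Otsu; the
exposed-surface stain is the primary engulfment indicator where bimodal,
and the actin criterion takes over only when the exposed channel is
uninformative (uniform: all-zero means fully internalized, uniformly
bright means fully exposed — the live-imaging case with no surface stain
additionally supports a manual axis override).  Combining the channels
with a plain OR would annex the ~1 µm actin-band skirt beyond the rim into
the mask and bias the fraction engulfed by ≈ +0.12 on rim-banded cups,
which is why the hierarchy above was chosen.  The mask is morphologically
closed on the mesh graph (one dilate/erode step) and the largest covered
component is kept.

Fraction engulfed is the area fraction of triangles weighted by their
covered-vertex count.  The phagocytic axis runs from the area-weighted
contact centroid through the mesh centroid; alignment is a Rodrigues
rotation of that axis onto +z (azimuth about the axis is arbitrary).
Axial profiles average deviation, radius and signals area-weighted in 30
bins of x.  Constriction is the largest azimuthal-mean inward radial
deviation over bins (the radially symmetric deformation component);
its bin-averaging attenuates a 1 µm-wide, 0.2 µm-deep ring to ≈ 0.18 µm.
Relative elongation is (axial extent)/(2 R<sub>eq</sub>) − 1 — one
consistent reading of the usual schematic definition.  The actin band
width is the FWHM of the binned profile converted to arc length; the
behind-peak intensity is interpolated 3 µm toward the base from the peak.
The Mollweide map inverts the projection per raster pixel and samples the
nearest vertex; because the projection is equal-area, the raster mean
equals the surface mean to < 1 %.

## Elasticity: forward solver

Interior Navier solutions of a homogeneous solid sphere, regular at the
origin, per real spherical-harmonic mode: the harmonic-gradient family
∇(r^l Y), the graded family r²∇(r^l Y) + γ_l **x** r^l Y with
γ_l = −[(4l+2)(1−2ν) + 2l]/(l + 5 − 4ν), and the toroidal family
r^l (r̂ × ∇_s Y).  Boundary tractions follow from the standard
traction formulas on a constant-radius surface.  The displacement→traction
map is block-diagonal in degree: a 2×2 spheroidal block and a toroidal
scalar μ(l−1)/R per degree.  Rigid translations (degree-1
harmonic-gradient) and rotations (degree-1 toroidal) map to zero traction
by construction.  Verified against closed forms: uniform pressure
u_r = −pR(1−2ν)/E exact to machine precision for ν ∈ {0.3, 0.45, 0.49};
Betti reciprocity of the per-degree blocks; exact degree diagonality.

The traction→displacement direction (used by the Hertz simulation and the
fixture generator) inverts each block; degree-1 spheroidal tractions are
resolved by least squares (the net-force-carrying part has no static
solution and the rigid part is unobservable), and degree-1 toroidal (net
torque) maps to zero.

## Elasticity: inverse problem

Free variables are the tangential (spheroidal l ≥ 1, toroidal l ≥ 2)
displacement coefficients up to l_max = 20; the radial coefficients are
fixed by the observed shape.  All three cost terms are nondimensionalized
(lengths by R₀, stresses by E, areas by R₀²) before summing with
α = β = 1: the stored energy E_el = ½∮T·u dA, the residual
R² = ∮_{outside mask} |T|² dA on a Gauss–Legendre grid (48×96 for
l_max = 20), and the anti-aliasing penalty E_pen = Σ w_l ‖T_l‖² with
w_l = (l/l_max)^8 acting on traction power — a steep high-pass that
suppresses Gibbs ringing while leaving l ≤ 10 essentially untouched
(exponent configurable).  Because every term is a quadratic form and the
constraint is linear, the minimizer is obtained by one symmetric
positive-definite solve; no iteration is required, and the solution is the
exact minimum of the same convex objective an iterative optimizer would
approach.

Two identifiability choices matter:

* **Degree 0 is excluded from the shape constraint.**  For ν → ½ the
  compliance of the uniform-compression channel vanishes
  (u_r ∝ (1−2ν)), so its stiffness (3λ+2μ ≈ 50 E at ν = 0.49) amplifies
  nanometer-scale mean-radius artifacts — e.g. the second-order
  |u_t|²/2R term in measured radii — into hundreds of Pa of spurious
  isotropic pressure.  Measured effect on the synthetic round trip:
  29 % → 3 % relative L2 error.  Cellular tractions carry no isotropic
  volume change of an incompressible target, so nothing physical is lost.
* **Radial coefficients are fitted, not interpolated.**  The SH
  coefficients of the observed radius are obtained by least squares over
  the mesh vertices (quasi-uniform directions), which keeps
  mesh-resolution noise out of the high degrees where the elastic
  stiffness (∝ l, and ∝ λ for incompatible modes) would amplify it.

The synthetic traction generator draws a random radial boundary
displacement (flat per-degree power, degrees 2…l_gen) and completes it
with the minimum-energy tangential field before forward-solving.  This
produces band-limited, equilibrium (zero net force and torque), seeded
fields — and places them in the class identifiable from shape-only data.
That restriction is not cosmetic: a fully random tangential field is
invisible to any shape-matching method (tangential motion of material
points does not change the surface), so round-trip recovery is only
meaningful on this class.  Measured recovery at l ≤ 8, 200 Pa peak,
E = 1.4 kPa, R = 3.7 µm: ≈ 3 % relative L2 error from a 3000-vertex mesh,
≈ 20–25 % with 10 nm RMS white radial noise added.

Region force integrals use Gauss–Legendre quadrature on the field's own
grid; the rim "contractile ring" is the band of arc half-width 1 µm
(configurable) around the constriction peak.

## Hertz indentation simulation

Teeth are rigid spheres (radius R_teeth, default 0.5 µm) indenting an
incompressible elastic sphere (R_target = 3.7 µm, E = 1.4 kPa) to depth d:
E* = 4E/3, 1/R_eff = 1/R_teeth + 1/R_target, F = (4/3)E*√R_eff d^{3/2},
a = √(R_eff d), p(r) = p₀√(1−(r/a)²), p₀ = 3F/(2πa²), with r the
great-circle distance from the contact point.  Ten teeth sit equally
spaced on the equator; overlap of contact zones is rejected.  The summed
pressure map is expanded to l_max = 40 (analysis on an internal 123×241
Gauss–Legendre grid so truncation, not aliasing, limits accuracy; the
reporting grid is the conventional 61×121), converted per degree to
boundary displacement at ν = 0.499 (the incompressible limit is
singular), and evaluated for two observables: the **effective tooth
depth** (inward radial displacement at a tooth center — generally smaller
than the imposed Hertz d, because it is the global response of the sphere
rather than the local contact solution; with a single well-resolved tooth
the two agree within a few percent) and the **average equatorial
constriction** (mean inward displacement over 720 equator points,
contact zones included, read literally; a contact-excluded variant is also
reported).  At l_max = 40 a 0.3 µm contact radius is marginally resolved:
the per-zone force from the 1-D arc quadrature matches the Hertz F to
0.05 %, while grid quadrature of the band-limited map matches total force
to ~0.3 % (2 % at l_max = 30).  Constriction increases monotonically in
both d and R_teeth across the 5×5 default sweep.

## Synthetic data

Scenes are defined analytically: base radius minus cosine-taper dimples
(depth attained exactly at center, zero outside the footprint), minus
axisymmetric ring grooves, plus an optional seeded band-limited radial
perturbation.  Cup fixtures place the contact mask as a polar cap around
−z (boundary colatitude from the cap-area inversion arccos(1−2f)), an
actin band (Gaussian, FWHM 2 µm, amplitude 100 a.u.) centered at a
configurable normalized axial position (default: the rim), tooth dimples
with co-located actin spots (amplitude 200 a.u.) on the boundary circle,
and an exposed-surface channel lit only outside the mask.

Rendering supersamples each axis to ~0.1 µm, evaluates a near-sharp
analytic edge (volume mode) or a Gaussian shell of σ = 0.1 µm (surface
mode), convolves with the anisotropic PSF and block-averages down to the
acquisition grid — point-sampling a sharp edge at voxel centers would
quantize the apparent edge to half-voxel positions (a ~0.1 µm artifact
along z that the supersampling removes).  Defaults are
spinning-disk-like: voxels 0.2×0.2×0.4 µm, PSF σ 0.15/0.15/0.4 µm; these
are fixture conventions, not claims about any particular instrument.
Noise is Poisson at a configurable photon scale (SNR ≈ √(I·scale)) plus
Gaussian background; every stochastic output is a pure function of
(spec, seed).

What the generator does **not** emulate: refractive-index mismatch,
depth-dependent aberrations, deconvolution artifacts, cell
autofluorescence bleed-through, multi-particle scenes, or non-star-shaped
deformations.  Passing tests therefore demonstrate correctness of the
analysis chain under the stated image model, not robustness to every
property of real microscopy data.

## Teeth analysis

A vertex belongs to a tooth candidate when its radial deviation is below
−δ (δ = 75 nm) AND its actin intensity exceeds median + 2·MAD.  Connected
components on the mesh graph are fused when their deviation-weighted
centroids lie within 0.3 µm geodesically; per tooth: equivalent-area
diameter (2√(A/π)), depth (largest inward deviation), mean actin, minimal
great-circle distance to the mask boundary (at-rim if ≤ 1.5 µm).  These
thresholds were chosen to recover the planted fixtures at the reported
tooth scale (~1 µm, ~200 nm) and are all configurable; with the
cosine-taper profile the −75 nm level set of a 1 µm tooth has equivalent
diameter ≈ 0.75 µm, so detected diameters read ~25 % low by construction.
Tracking is greedy mutual-nearest-neighbor linking between consecutive
frames on great-circle distance, gated at 0.5 µm per frame (no identity
swaps beyond the gate); track speed is the mean over per-step
GCD/Δt.  Planted 0.094 µm/s drifts are recovered within a few percent.

## Determinism and I/O

All randomness flows through `numpy.random.default_rng` with explicit
seeds derived from one global seed; CSV/JSON writers use fixed float
formats and sorted keys, so identical configuration + seed reproduces
byte-identical outputs (tested).  Stacks are OME-TIFF (channel names and
physical pixel sizes in metadata; a spacing override is required when
metadata is absent), meshes are ASCII PLY with per-vertex scalar
properties, tables are CSV with an optional units row.

## Problem sizes

Default sizes balance accuracy against desk-scale runtimes: 3000 surface
directions, inference at l_max = 20 on a 48×96 grid (~1 s per particle),
Hertz simulation at l_max = 40 (~15 s for a 5×5 sweep with shared bases),
rendering ~10⁶ supersampled voxels (~1 s).  A full pipeline run on one
fixture takes well under a minute on one CPU.

## Known limitations

* Small-strain linear elasticity only (ε ≲ 0.1 enforced); no
  viscoelasticity or finite-strain corrections.
* The shape constraint identifies the radial displacement with the radius
  change along fixed directions — exact only to first order in u/R.
* The anti-aliasing weight w_l = (l/l_max)^8 is a design choice; the
  original penalty's exact functional form is not published, so agreement
  is established against analytic limits and round trips rather than
  against the original implementation.
* Tooth-detection thresholds are fixture-calibrated substitutes for
  unpublished criteria and should be re-tuned on real data.
* Mask determination assumes a bimodal exposed-surface stain; uniform
  channels fall back to actin or to a manual override.
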