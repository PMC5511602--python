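# Methods

`axonvar` implements, at desk scale, the computation chain that links the
geometry of white-matter fiber bundles — as seen by diffusion tensor
imaging (DTI) — to strain-based predictors of traumatic brain injury in
anisotropic finite-element (FE) head models. Real studies of this kind
run on cohort diffusion MRI and a full transient head simulation; here a
synthetic-data module replaces both, so that every stage can be tested
against known ground truth. This note documents the models, the choices
made where the design was open, and what the synthetic conditions do and
do not establish about real data.

## Tensor estimation

The diffusion signal is modeled as mono-exponential,
`S = S0 exp(-b gᵀ D g)`, and fitted per voxel in the log domain by
two-pass weighted linear least squares (WLLS): an ordinary LS pass gives
predicted signals, whose squares become the weights of a single
re-weighted solve. One reweighting iteration is the common practice for
this estimator; the weights compensate for the fact that log-transformed
noise scales inversely with signal. Only shells with b < 1500 s/mm²
enter the fit (the mono-exponential model degrades at higher b), with at
least six distinct gradient directions required. All b = 0 volumes are
averaged into a single S0 regressor row for conditioning. Negative
eigenvalues of the fitted tensor are set to zero and the tensor
reassembled, guaranteeing positive semidefiniteness. Voxels containing
non-positive signals are excluded from the mask rather than patched.

Fractional anisotropy follows the standard normalized eigenvalue
dispersion; the all-zero eigenvalue triple is defined as FA = 0 to avoid
0/0, and results are clipped to [0, 1] against round-off only.

## Tractography

Deterministic streamline tracking integrates the unit principal
eigenvector field with a fourth-order Runge–Kutta scheme at a fixed
0.5 mm step, bidirectionally from each seed. Design choices where the
procedure is conventionally underdetermined:

* **Interpolation** — component-wise trilinear interpolation of the
  tensor, re-diagonalized at the interpolated point. This keeps the
  direction field smooth and is the standard choice for tensor-field
  tracking; nearest-neighbor directions would quantize curvature.
* **Sign handling** — eigenvectors are axial; each RK4 stage direction
  is sign-aligned with the previous one, and the seed direction is
  canonicalized (non-negative z, ties broken toward y then x) so point
  ordering is deterministic across subjects.
* **Stopping rules** — interpolated FA below 0.2; turning faster than
  40° per mm, discretized as >20° between successive 0.5 mm step
  directions; leaving the volume; or a step cap. Seeds in sub-threshold
  FA, outside the volume, or on degenerate tensors are rejected with
  reason codes.
* **Seeding** — one seed per voxel center of the region of interest
  (ROI) after a one-voxel binary erosion (6-connected, border counts as
  background), which drops boundary fibers. No jitter: tracking is
  bit-reproducible. Fibers shorter than 10 mm are discarded.

Step spacing is exact by construction (the combined RK4 direction is
re-normalized), so the fiber length is step × (n − 1).

## Along-tract descriptors

Each fiber r(s) is described by its unit tangent T(s) (central
differences inside, one-sided at the endpoints), the elevation/azimuth
pair Θ ∈ [0, π], Φ ∈ [0, 2π) of T in the fixed laboratory frame, and the
curvature k(s) = |dT/ds|. Within an ROI, fibers are aligned to the
reference fiber — the one passing closest to the ROI centroid (the
voxel-count centroid, not the bounding-box center) — by matching each
fiber's seed to the nearest reference point within ±12 mm of reference
arc length; matches that saturate the window are flagged. Profiles then
share a signed arc-length grid at the 0.5 mm step spacing, so binning is
exact and no resampling is needed.

Statistics are two-stage: within subject across fibers, then across
subjects (sample SD, CV = 100·SD/mean). Angle statistics are computed on
the scalar Θ, Φ values — matching how such profiles are conventionally
reported — with Φ unwrapped along each fiber before averaging to avoid
the 0/2π seam. Circular averaging across the seam between subjects whose
mean azimuths straddle 0 is a known residual limitation.

## DTI-to-FE coupling

Voxel centers are assigned to the hexahedral element containing them
(interval tests for axis-aligned meshes, with a fast lattice lookup for
regular grids; face ties go to the lower element index). Each element's
tensor is the weighted average of its voxels with weights e^(−Dᵢ), where
Dᵢ is the voxel-center-to-element-centroid distance normalized by the
largest such distance within that element's voxel set. This
normalization — one of several defensible readings of a "normalized
distance" — bounds Dᵢ to [0, 1] so weights span [1/e, 1] regardless of
element size. A single-voxel element gets D = 0. Elements without voxels
inherit the mean tensor of their face neighbors (iterated) and are
logged loudly; a coupled model should never silently contain data-free
brain elements.

Element FA is discretized into nine intervals that set the fiber
dispersion parameter k of the constitutive model:

| FA interval | k | part |
|---|---|---|
| [0.0, 0.2) | 0.3333 | 0 (gray) |
| [0.2, 0.3) | 0.2732 | 1 |
| [0.3, 0.4) | 0.2500 | 2 |
| [0.4, 0.5) | 0.2273 | 3 |
| [0.5, 0.6) | 0.2000 | 4 |
| [0.6, 0.7) | 0.1667 | 5 |
| [0.7, 0.8) | 0.1282 | 6 |
| [0.8, 0.9) | 0.0769 | 7 |
| [0.9, 1.0] | 0.0000 | 8 |

Intervals are half-open with the last closed at 1.0 (the printed bounds
touch; an inclusion rule had to be fixed, and it is tested at the
boundaries). FA < 0.2 is treated as gray matter: isotropic, k = 1/3.
The element fiber vector P is the principal eigenvector of the averaged
tensor, sign-canonicalized and exported with its elevation/azimuth
angles and an orthogonal companion vector in an orthotropic-keyword-style
text block. Averaging differently oriented voxels lowers element FA
relative to the voxel data — a smoothing the coupled models inherit by
construction, visible in the composition tables.

## Constitutive model

The brain is a Gasser–Ogden–Holzapfel (GOH) fiber-reinforced
hyper-viscoelastic solid with energy per reference volume

W = G/2 (Ĩ₁ − 3) + K ((J² − 1)/4 − ln J / 2) + k₁/k₂ (e^{k₂⟨Ẽₐ⟩²} − 1),

with J = det F, C̃ = J^(−2/3) FᵀF, Ĩ₁ = tr C̃, Ĩ₄ = n₀·C̃n₀, and the
generalized fiber (axonal) strain

Ẽₐ = k (Ĩ₁ − 3) + (1 − 3k)(Ĩ₄ − 1).

k is the dispersion parameter from the FA table (1/3 isotropic, 0
perfectly aligned), making Ẽₐ independent of n₀ exactly when k = 1/3.
The "− 1" in the Ĩ₄ term is the standard GOH form and is used
consistently (printed variants of this energy sometimes drop it in one
place). The Macaulay bracket is read as tension-only on Ẽₐ, i.e.
⟨Ẽₐ⟩², since squaring first would make the bracket a no-op. Defaults:
G = 2990 Pa, K = 50 MPa (near-incompressible), k₂ → 0 evaluated through
its analytic limit k₁⟨Ẽₐ⟩² (switched below k₂ = 1e-8), and k₁ = 100 Pa
as a placeholder — the fiber stiffness is location-dependent in real
models and left as a required parameter; the axonal strain itself does
not depend on k₁.

The Cauchy stress is the exact derivative of W (volumetric part plus
deviatorically projected isochoric part), verified against central
differences of the energy over randomized states. Viscoelasticity is
quasi-linear on the **isochoric** second Piola–Kirchhoff stress only,
with the six-term Prony relaxation function

g(t) = M∞ + Σ Mᵢ e^(−t/τᵢ),  τ = 10⁻⁶ … 10⁻¹ s,
M = (0.7685, 0.1856, 0.0148, 0.0190, 0.0026, 0.0070), M∞ = 0.0025,

whose coefficients sum to 1 exactly, so g(0) = 1 recovers the
instantaneous hyperelastic response. The convolution uses the standard
recursive exponential update, exact for piecewise-linear stress within a
step; the step size comes from the input history. Keeping the volumetric
part elastic is the common choice for near-incompressible brain models
and keeps the volumetric response well-posed; applying relaxation to the
full stress is the main alternative and was not taken.

## Injury metrics and population statistics

Under a prescribed deformation history F(t) (ramps from the identity:
isochoric uniaxial stretch, simple shear, rigid rotation, volumetric
expansion — or any user-supplied history), each material point yields
the axonal strain trace and the largest eigenvalue of the
Green–St. Venant strain E = (FᵀF − I)/2. The scalar predictors are the
worst-case peaks over time, MAS and MPS, independent of when they occur.
Because histories start at the identity, the axonal-strain maximum is
never negative; a defensive clamp-and-flag exists for externally
supplied series.

Regional peaks take the maximum over a region's elements (ties to the
lower element id) with the argmax element centroid as the peak location
(element centroids are unique; nodes are shared). Across subjects:
sample SD and CV per region; loading conditions are compared with a
two-sample t test for equality of means — pooled variance by default,
Welch behind a flag, and the zero-variance degenerate cases defined
explicitly (equal means → t = 0, p = 1; unequal → p = 0). Peak-location
dispersion removes outliers per axis by the 1.5·IQR rule ("disregarding
outliers" needs an operational definition) and reports the product of
the remaining per-axis ranges in cm³. No multiplicity correction is
applied across regions.

## Synthetic data: what it emulates and what it does not

Phantoms are single-fiber-population bundles: a tube of prescribed
radius around an analytic centerline (straight, circular arc, u-shaped
half-turn in the transverse plane emulating callosal geometry, or an
inclined helix emulating a corticospinal-like course). In-bundle voxels
hold cylindrically symmetric (prolate, λ₂ = λ₃) tensors whose principal
axis is the local centerline tangent and whose FA and mean diffusivity
are prescribed exactly — the prolate eigenvalues are obtained in closed
form from FA and MD, which is unique and invertible. The tube is
open-ended: voxels beyond the centerline ends are background, so tracked
fibers terminate at the bundle ends instead of growing straight tails.
Out-of-bundle voxels are prolate with the (usually zero) background FA.
Defaults: FA 0.6 inside — mid-range for major white-matter tracts — and
MD 0.7e-3 mm²/s, 1 mm voxels.

DWI simulation inverts the mono-exponential model and adds Rician noise
as the magnitude of a complex signal with independent N(0, σ²)
perturbations — the standard MR magnitude noise model. σ has no
principled default (the effective noise of preprocessed cohort data is
not knowable here) and is a free parameter; the recovery analyses run
noiseless, so they measure the pipeline's geometric fidelity, not its
noise robustness.

Cohorts perturb a base phantom per subject: a rigid tilt by a signed
angle ~ N(0, angle_sd) about a random axis drawn **perpendicular to the
base fiber direction** — so the drawn angle equals the resulting change
of fiber direction exactly, which is what makes signed recovery and the
3-standard-error comparisons well defined — plus an FA offset
~ N(0, fa_sd) (clipped to [0, 0.99]) and an extent offset ~ N(0,
length_sd). Each subject's random stream derives from (seed,
subject_id), so any subject is reproducible in isolation. The recovery
conditions used throughout are n = 485 subjects, angle_sd = 10°,
fa_sd = 0.05 on a 32³ grid — a cohort size at which the standard error
of a sample SD is about σ/√(2n), small enough to make recovery a sharp
test — with the cohort test sized to minutes, not hours, by the 32³
volume and a single-seed ROI.

What passing these tests shows: the chain fit → track → descriptors →
coupling → material → statistics preserves orientation and FA dispersion
without attenuation or inflation, and the orientation sensitivity of MAS
versus MPS emerges from the constitutive anisotropy alone. What it does
not show: robustness to crossing fibers, realistic anatomy, registration
error, EPI/eddy artifacts, or measurement noise — none of which the
generator emulates — nor anything about a full transient head simulation
with contacts and heterogeneous parts, which is out of scope by design.

## Numerical details

* Eigen-decompositions use symmetric solvers; degenerate principal
  directions (λ₁ ≈ λ₂ within a relative 1e-6) are flagged, not guessed.
* The direction sign convention (z, then y, then x non-negative) is
  applied at seeds, to exported element vectors P, and before computing
  element orientation angles.
* The deliberate boundary rules — FA intervals half-open, voxel face
  ties to the lower element, alignment-window saturation flags, t-test
  degeneracies — are each pinned by a test.
* Toy meshes are axis-aligned with right-handed brick connectivity;
  volumes are computed by tetrahedral decomposition, so the code does
  not assume axis alignment.
* All world coordinates are mm via the image affine; voxel indices are
  0-based.
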