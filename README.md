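# axonvar

How much does person-to-person variability in white-matter fiber
geometry move the needle on strain-based predictors of traumatic brain
injury? Anisotropic finite-element (FE) head models read the local fiber
direction from diffusion tensor imaging (DTI) and report the tissue
stretch **along** the fibers — the axonal strain — as an injury metric.
Because that metric depends on fiber orientation, its reliability across
a population hinges on how biological variability in tract geometry
propagates through the whole modeling chain.

`axonvar` implements that chain end to end at desk scale, for
researchers in injury biomechanics and diffusion MRI methods:

1. **Tensor estimation** — weighted linear least squares on the
   b < 1500 s/mm² shells of a diffusion-weighted acquisition, negative
   eigenvalues clamped, FA and principal-direction maps
   (`axonvar.tensor_fit`).
2. **Tractography** — deterministic RK4 streamline tracking of the
   principal eigenvector field (0.5 mm steps, stop at FA < 0.2 or turns
   over 40°/mm, seeds from one-voxel-eroded ROIs, 10 mm length filter)
   (`axonvar.tractography`).
3. **Along-tract descriptors** — fiber length l = Δm(n−1), unit tangent
   **T**(s), elevation/azimuth angles (Θ, Φ), curvature k(s) = |d**T**/ds|,
   alignment of a bundle to its reference fiber within a ±12 mm window,
   and two-stage (within-subject, then across-subject) profile statistics
   (`axonvar.fiber_descriptors`).
4. **DTI-to-FE coupling** — element tensors by distance-weighted voxel
   averaging, DiffT_elem = Σ DiffTᵢ e^(−Dᵢ) / Σ e^(−Dᵢ); element FA
   discretized into nine intervals that set the fiber dispersion
   parameter k (FA < 0.2 → gray matter, k = 1/3) and the element fiber
   vector **P**(Θ, Φ) (`axonvar.fe_coupling`).
5. **Constitutive model** — Gasser–Ogden–Holzapfel fiber-reinforced
   hyper-viscoelasticity: W = G/2(Ĩ₁−3) + K((J²−1)/4 − ln J/2) +
   k₁/k₂(e^{k₂⟨Ẽₐ⟩²}−1), with the axonal strain
   Ẽₐ = k(Ĩ₁−3) + (1−3k)(Ĩ₄−1), exact Cauchy stress, and a six-term
   Prony series applied quasi-linearly to the isochoric stress
   (`axonvar.material_model`).
6. **Injury statistics** — per-region peaks of axonal strain (MAS) and
   principal Green–St. Venant strain (MPS) across subjects, CVs,
   two-sample t tests between loading conditions, and the dispersion of
   the peak location after 1.5·IQR outlier removal
   (`axonvar.strain_stats`).

A first-class synthetic-data module (`axonvar.synthetic_data`) supplies
everything a cohort study needs with known ground truth: curved
single-fiber tensor phantoms (straight / arc / u-shaped callosal-like /
helical corticospinal-like), Rician-noised DWI signals, populations with
controlled angular and FA dispersion, toy hexahedral meshes, and
deformation-gradient histories. `axonvar.pipeline` chains all stages for
a whole cohort; `docs/methods.md` documents the models and choices.

## Worked example

The numbered scripts under `analysis/` run a 25-subject study on a
straight bundle phantom (FA 0.6, tilt SD 10°, FA SD 0.05) and write
their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_tensors.py
python analysis/03_track_descriptors.py
python analysis/04_couple_mesh.py
python analysis/05_material_peaks.py
python analysis/06_population_stats.py
```

Selected output (deterministic for the committed seed):

```
per-ROI FA across subjects (two-stage):
  ROI 1: mean 0.6028  SD 0.0518  CV 8.60%  (n = 25)
generating values: mean 0.6, SD 0.05 (CV 8.33%)
```

The fitted-and-averaged FA statistics reproduce the dispersion that was
put into the cohort: the pipeline neither attenuates nor inflates
inter-subject FA variability.

```
elevation angle: mean 9.08 deg (folded-normal expectation 9.24), SD 6.95 deg (expectation 6.98)
```

Tracked fiber elevation angles recover the magnitude of the generating
tilts (for tilts ~ N(0, s), the unsigned elevation follows a folded
normal).

```
condition a: MAS 0.0434 +/- 0.0044 (CV 10.20%)   MPS 0.0512 +/- 0.0000 (CV 0.00%)
condition b: MAS 0.0916 +/- 0.0089 (CV 9.69%)   MPS 0.1050 +/- 0.0000 (CV 0.00%)
t test a vs b: MAS t=-24.28 p=1.31e-28 **   MPS t=-inf p=0.00e+00 **
MAS localization (condition b): axis ranges [ 4.  4. 20.] mm, volume 0.32 cm^3
```

Under identical loading, MAS varies across subjects (CV ≈ 10%) because
it projects the strain onto each subject's fiber directions, while MPS —
orientation-blind — does not vary at all; yet both metrics still
separate the milder condition a (stretch 1.05) from the harsher
condition b (stretch 1.10) decisively, and the location of the peak
axonal strain stays confined to a sub-cm³ volume. That is the core
finding this pipeline exists to probe: axonal strain is
orientation-sensitive but remains a usable population-level injury
predictor.

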