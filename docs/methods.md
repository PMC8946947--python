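# Methods

`ironmap` implements an automated pipeline for differentiating parkinsonian
syndromes — Parkinson's disease (PD), the parkinsonian and cerebellar variants
of multiple system atrophy (MSA-P, MSA-C), and progressive supranuclear palsy
(PSP) — from the topography of iron deposition in deep gray matter on
susceptibility weighted MRI (SWI). This note documents the model, the choices
made where the design was open, and what the synthetic validation does and
does not establish.

## Pipeline

1. **Preprocessing.** The T1w volume is scaled by one global factor so its
   mean white-matter intensity equals 110 (the conventional white-matter
   anchor); the SWI volume is aligned to the T1w grid by intensity-based
   affine registration.
2. **Hybrid contrast (HC).** `HC = w1·T1w + w2·SWI`, with `(w1, w2)` chosen
   to minimize the squared difference between the HC putamen/pallidum mean
   intensities and those of a reference template with strong deep-gray
   delineation:

   `(w1*, w2*) = argmin ‖ [[I_put^T1w, I_put^SWI], [I_pall^T1w, I_pall^SWI]] (w1, w2)ᵀ − (I_put^ref, I_pall^ref)ᵀ ‖²`

   The 2×2 system is solved exactly (residual 0) when non-singular; a
   condition-number threshold rejects collinear T1w/SWI contrast. The ROI
   means on the subject side come from the *initial* deep-gray mask (an
   input: atlas- or truth-derived); the template means from the template's
   own label map. Negative weights are allowed — the solve routinely returns
   `w1 < 0` because the phantom T1w has nearly inverted nucleus/WM contrast
   relative to the template; a flag can enforce non-negativity.
3. **Segmentation.** The template deep-gray labels are carried to the subject
   by registering the subject's HC image to the template and transporting
   labels through the inverse mapping with nearest-neighbor interpolation
   (labels are never invented). Non-linear engines are not re-implemented:
   `DeformationProvider` accepts an externally computed dense displacement
   field on the template grid, and the in-repo default is the affine engine —
   sufficient for the affinely generated phantoms used in validation.
4. **Radiomics.** Features are extracted from the SWI intensities inside the
   propagated putamen mask (left and right merged into one ROI, which
   maximizes voxel support for the distance-7 statistics).
5. **Selection.** Fisher score
   `F_r = Σ_c n_c(μ_rc − μ_r)² / Σ_c n_c σ²_rc` (population variances;
   zero-denominator rule: ∞ if the numerator is positive, else 0), top 10,
   computed on training subjects only, re-done inside every split.
6. **Classification.** For each of the 6 disease pairs: stratified 7:3
   split, z-score standardization fit on train, Fisher top-10 on train, 10
   classifiers tuned by 3-fold cross-validation on train over minimal fixed
   grids, refit on the full training set; metrics are AUC, balanced accuracy
   `(Sen+Spe)/2`, sensitivity, specificity and accuracy, averaged over 100
   repeats (the default; the test suite and acceptance script use 20).

## Radiomic features

178 uniquely named features per ROI: 19 first-order, 10 shape-2D, 16
shape-3D, 72 GLCM (24 features × neighbor distances 1, 4, 7), 16 GLRLM, 16
GLSZM, 15 NGTDM (5 × distances 1, 4, 7), 14 GLDM. Names follow the
`class_FeatureName` convention with a trailing distance digit for the
distance-parameterized families (`glcm_Autocorrelation7`).

Numerical conventions:

- **Discretization** — fixed bin width, default 25 intensity units:
  `level = floor((x − min)/W) + 1`. Distances are measured in voxels (a
  config flag converts mm). A constant ROI collapses to a single level.
- **GLCM** — 13 unique 3D directions, symmetric accumulation, per-angle
  normalization, features averaged over angles; angles with no valid pair at
  a distance are skipped; if *no* angle has a pair the distance is flagged
  and its features set to 0 rather than silently dropped.
  Degenerate guards: Correlation = 1, Imc2 = 0 and MCC = 0 for single-level
  ROIs.
- **GLRLM** — runs enumerated along the 13 directions, features averaged.
- **GLSZM** — zones are 26-connected equal-level components.
- **GLDM** — dependence = count of 26-neighbors within `alpha` (default 0)
  gray levels of the center; the stored matrix is indexed by that raw count
  (an isolated voxel has dependence 0), while feature formulas weight
  dependence as count + 1 (the center belongs to its own dependence set),
  keeping small-dependence emphases finite.
- **NGTDM** — neighborhood is the Chebyshev cube of radius δ; voxels with no
  in-ROI neighbor are excluded; Coarseness uses a 1e-30 denominator guard;
  Busyness and Strength are 0 when their denominators vanish.
- **First-order** — population moments; Entropy/Uniformity use the same
  fixed-bin-width histogram as the texture families. Nine features that read
  the raw signal level (Minimum, Maximum, Mean, Median, 10th/90th
  percentiles, Range, RootMeanSquared, TotalEnergy) are tagged signal-based
  and excluded from selection, because SWI intensity is not a quantitative
  susceptibility measure; only distribution-shape features pass the filter.
- **Shape** — mesh quantities come from marching cubes on the binary mask
  after a 0.7-voxel Gaussian pre-smoothing, which suppresses the staircase
  artifact that otherwise inflates surface area (a digitized ball meshes to
  sphericity ≈0.99 instead of ≈0.92) at the cost of <2% mesh-volume
  shrinkage; tiny structures that would smooth below the iso-level are
  meshed raw. The 16-name 3D set includes Compactness1/2 alongside the 14
  commonly enabled names; the 2D set is computed on the axial slice with the
  largest cross-section.

Every texture matrix is checked against an exhaustive brute-force
enumeration (pair counting, run walking, flood fill, neighborhood scans)
written independently in the test suite; feature formulas are checked
against closed forms on degenerate ROIs and independent statistics routines.

## Registration

Intensity-based affine registration uses a multi-resolution Mattes
mutual-information criterion (mean squares available for same-modality
cases), regular-step gradient descent, geometry-centered initialization, and
optionally seeded subsampling. The `fast()` preset (2-level pyramid, 25%
seeded sampling) is ~20× faster on 64-voxel grids with near-identical
alignment quality and is used for cohort-scale synthetic runs. Failure to
converge raises an error carrying the final similarity value.

## Synthetic cohorts

The generator renders parametric "brains": an ellipsoidal white-matter shell
with bilateral putamen and globus pallidus. T1w has weak deep-gray contrast
and is nearly iron-blind; SWI carries the class-specific hypointensity:

- **MSA-P** — posterolateral putaminal hypointensity with a lateral-to-medial
  gradient, plus a lateral pallidal rim;
- **PSP** — anteromedial pallidal hypointensity over a moderate pedestal,
  mild diffuse putaminal change;
- **PD** — a slit along the lateral putaminal margin with a mild core;
- **MSA-C** — mild diffuse putaminal change.

Two design decisions matter for interpretation:

1. **Pattern, not amount.** The putaminal fields of all classes are
   normalized per subject to the same mean signal drop (default 20% of the
   depth scale × a log-normal severity). Classes therefore cannot be told
   apart by overall putaminal signal level — only by the spatial arrangement
   of the hypointensity. This encodes the clinical observation that putaminal
   hypointensity per se is nonspecific and age-related, while its topography
   is disease-specific; it is also what makes the segmentation comparison
   meaningful, since a misplaced mask loses the pattern rather than the
   amount.
2. **Scanner-like nuisance.** Each subject draws a log-normal SWI receive
   gain (σ=0.08), a global offset (SD 5), a smooth intensity-inhomogeneity
   field (amplitude 8, correlation length 12 voxels), Gaussian noise (SD 10
   on a ~150 baseline), per-subject pattern-parameter jitter (gradient
   emphasis, slit width) and a small random affine of the whole anatomy.
   Without these terms every mask — even a deliberately misplaced one —
   classifies at AUC 1.0 and the mask comparison is degenerate; with them
   the phantom task difficulty sits in the regime the method is designed
   for (truth-mask AUC ≈0.95, HC-mask ≈0.88 on MSA-P vs PD at the default
   64³ grid, 34/56 subjects, 20 repeats).

A consequence of the gain/offset nuisance is that intensity-scale-sensitive
texture features (e.g. GLCM Autocorrelation) lose most of their univariate
effect (d ≈ 0.6 between MSA-P and PD), while scale-robust co-occurrence
features (Id4 ≈ 2.6 SD, Imc24 ≈ 2.4 SD) carry the separation — the
separability check therefore reads the strongest distance-4 GLCM feature.

The iron-blind surrogate used in the mask comparison is a mirror-symmetric
medial drift of the propagated mask (3 voxels toward the midline per
hemisphere + 2 anterior): the characteristic failure of an atlas-only
segmentation that includes non-iron tissue and misses the lateral iron rim.
A plain global shift is *not* a valid surrogate — it drags sharp
white-matter edges into the ROI, which adds class-discriminative texture and
raises AUC.

What phantoms do not emulate: real anatomy (nuclei are ellipsoids; no
cortex, CSF, vessels or mineralization), non-affine anatomical variability,
phase-related SWI artifacts, and the scanner's true noise spectrum. Passing
tests show the pipeline recovers a known, controlled signal under realistic
nuisance — not that it reaches any particular accuracy on patients.

## Classifier roster

kNN, linear SVM, RBF SVM, Gaussian process, random forest, decision tree,
multi-layer perceptron, AdaBoost, Gaussian naive Bayes, QDA — standard
library implementations behind the harness; the bespoke science is the
harness, not the fitters. Grids are minimal and fixed (e.g. kNN
k ∈ {3, 5}, SVM C ∈ {1, 10}); QDA is preceded by a 5-component PCA because
per-class covariances are rank-deficient at the per-fold class sizes this
cohort scale produces. "Train" metrics are out-of-fold cross-validated
predictions on the training set (resubstitution available by flag). The
repeat-r seed is `master_seed + r`; a degenerate draw (a class with fewer
than 3 training subjects) is redrawn with an offset seed and logged.

## Problem sizes used in validation

The test suite and acceptance script run: a 90-subject MSA-P/PD cohort
(34/56, the two largest diagnostic groups at their study sizes) for the
end-to-end mask comparison, a 40-subject zero-effect cohort for the null
check, 20 split repeats (down from the 100 of the full protocol), and 64³
1 mm grids. These sizes keep the full validation in a few CPU-minutes while
leaving every statistical conclusion comfortably clear of its threshold.

## Known limitations

- The affine deformation provider cannot express the local boundary errors
  that motivate hybrid contrast on real data; on affine phantoms the HC
  advantage is demonstrated through the misalignment surrogate instead.
- Feature values depend on the discretization bin width (default 25); no
  bin-width harmonization across scanners is attempted.
- The 2×2 weight solve uses two ROIs and two modalities; spatially varying
  weights and additional modalities are out of scope.
- Shape features are reported for completeness but are nearly
  class-uninformative on these phantoms by construction (shared geometry
  distribution across classes).
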