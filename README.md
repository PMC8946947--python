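# ironmap

Brain-iron radiomics from susceptibility weighted MRI (SWI), for
differentiating atypical parkinsonian syndromes.

Parkinson's disease (PD), the parkinsonian and cerebellar variants of
multiple system atrophy (MSA-P, MSA-C) and progressive supranuclear palsy
(PSP) share parkinsonian motor signs but differ in the topography of iron
accumulation in the deep gray nuclei: MSA-P shows posterolateral putaminal
hypointensity with a lateral-to-medial gradient, PSP an anteromedial
pallidal hypointensity, PD a nonspecific slit along the lateral putaminal
margin. `ironmap` turns those patterns into a classification pipeline:

1. **Hybrid contrast** — `HC = w1·T1w + w2·SWI`, with the weights solved
   from the 2×2 least-squares problem that matches the HC putamen/pallidum
   mean intensities to a reference template:
   `(w1*, w2*) = argmin ‖ M (w1, w2)ᵀ − (I_put^ref, I_pall^ref)ᵀ ‖²`,
   `M = [[I_put^T1w, I_put^SWI], [I_pall^T1w, I_pall^SWI]]`.
   The HC image keeps the registration-friendly anatomy of T1w and the iron
   sensitivity of SWI.
2. **Iron-reflecting segmentation** — template deep-gray labels propagated
   to the subject through registration of the HC image (affine in-repo; a
   deformation-provider interface accepts external non-linear fields).
3. **Radiomics** — 178 features per putamen ROI (19 first-order, 10+16
   shape, and GLCM/GLRLM/GLSZM/NGTDM/GLDM texture families), with GLCM and
   NGTDM computed at neighbor distances δ ∈ {1, 4, 7}; signal-level
   first-order features are excluded since SWI intensity is not quantitative.
4. **Fisher-score selection** — `F_r = Σ_c n_c(μ_rc−μ_r)² / Σ_c n_c σ²_rc`,
   top 10, computed on training subjects only.
5. **Evaluation harness** — 10 standard classifiers, stratified 7:3 splits,
   3-fold cross-validated tuning, AUC / balanced accuracy / sensitivity /
   specificity / accuracy averaged over repeated splits.

A seeded phantom generator renders paired T1w/SWI cohorts with ground-truth
masks and the class-specific iron topographies, so the whole pipeline is
testable without patient data.

## Worked example

```bash
python examples/01_hybrid_contrast.py
```

```
weights: w1 = -3.9738, w2 = 3.0857
residual of the 2x2 solve: 5.82e-26
template putamen mean:       73.397
fused HC putamen mean:       73.397
template pallidum mean:      58.094
fused HC pallidum mean:      58.094
```

The 2×2 system is non-singular, so the solve is exact (residual ~1e-26) and
the fused image's putamen and pallidum means reproduce the template targets
to machine precision; `w1 < 0` reflects the phantom T1w's weak, inverted
deep-gray contrast, and `w2 > 0` keeps SWI's iron-related hypointensity in
the hybrid image.

```bash
python examples/04_classification.py
```

```
RBFSVC  test AUC 0.987  bAcc 0.905  Sen 0.860  Spe 0.950
GNB     test AUC 0.978  bAcc 0.895  Sen 0.840  Spe 0.950
```

On a 35-phantom MSA-P vs PD cohort with ground-truth masks, the RBF-SVM
separates the two iron topographies with a mean held-out AUC of 0.987 over
10 repeated splits — high because the masks are exact; with propagated
masks the task gets harder, and that difference is exactly what the
package's end-to-end tests measure.

The other examples cover label propagation with Dice scoring
(`02_segmentation.py`) and the feature extractor (`03_radiomics.py`).

A thin CLI mirrors the stages
(`ironmap simulate | preprocess | fuse | segment | extract | select |
classify | run`); `ironmap run --config run.yaml` executes the whole
pipeline from a subject manifest.

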